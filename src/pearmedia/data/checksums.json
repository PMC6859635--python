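{
 "bbd_design.csv": "61ea5f4fe48ec39ec621df6bbd578a83c5f00f04239be7450d3e503afd589c6f",
 "ohf_responses.csv": "8fbc5df5ae9a4b37561a24ea1ea21582d13e3f29f89ae0dd349a655fccffad6c",
 "pyrodwarf_responses.csv": "aca81245232d705005050c1cf34a3cb1bed6996aedd520d63ed6894c2d7d5fdf"
}
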