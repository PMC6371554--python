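{
  "expected_cells.csv": "c74189e05a0d8c99c6ee9824902983835727b0ae086688b3708034c7560bfc7f",
  "packages.csv": "d192458d3ca6a7fbb311c2c03d54e37e18bebd115b0ab90f07adb507148378b5",
  "regimens.yaml": "364d0ab484258e6c0a887051176e81b85586248851c4b5508a7ab1ece1fbb12c",
  "reimbursement.csv": "8d510973ce04fb2d420822e1034ccdd4f6991e5facc4663b074c099820c40713"
}
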