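chloromethoxymethane
  nlamd

  4  3  0  0  0  0  0  0  0  0999 V2000
   -1.9070    0.0625    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.4450    0.5785    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
   -0.5617   -0.4483    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    2.0237   -0.1928    0.0000 Cl  0  0  0  0  0  0  0  0  0  0  0  0
  1  3  1  0
  3  2  1  0
  2  4  1  0
M  END
$$$$
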