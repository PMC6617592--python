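cultivar,fw_g,dw_g,pdm,lv,ploidy
1,525.00,154.15,0.29,16841584,2x
2,655.00,190.14,0.29,24446478,4x
3,391.42,130.49,0.33,17199440,4x
4,579.75,188.97,0.33,18919565,2x
5,498.39,141.70,0.28,22324398,2x
6,403.11,131.24,0.33,17012703,4x
7,370.61,126.08,0.34,14231352,2x
8,499.67,147.76,0.30,19571709,2x
9,514.49,171.25,0.33,20948934,2x
10,522.54,158.45,0.30,19316282,4x
11,475.96,161.89,0.34,20783519,2x
12,317.75,108.53,0.34,15633334,2x
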