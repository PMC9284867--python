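medicine_code,ME_n,ME_pct,MH_n,MH_pct,MD_n,MD_pct,OI_n,OI_pct,total
ANA1,13196020,39.67,9337267,28.07,5263653,15.83,5464512,16.43,33261452
DOC40,22886244,38.63,19535557,32.97,6095049,10.29,10729355,18.11,59246205
EXE25,16301476,50.07,4857270,14.92,6449958,19.81,4948653,15.2,32557358
LET25,6683805,56.11,573524,4.81,3549046,29.79,1105916,9.28,11912291
PAC6,26010194,57.78,8515488,18.92,4896219,10.88,5591795,12.42,45013696
TAM20,19865277,54.79,9197183,25.37,1604663,4.43,5589036,15.42,36256160
TRA440,79911241,10.86,195836172,26.62,174182648,23.68,285744659,38.84,735674721
VIN10,6305699,57.0,2153148,19.46,814825,7.37,1788105,16.16,11061777
VIN20,6338358,40.9,6429645,41.49,2498773,16.13,228920,1.48,15495696
VIN30,17960731,56.49,9193434,28.92,4351541,13.69,286020,0.9,31791725
TOTAL,215459045,21.28,265628688,26.24,209706375,20.72,321476971,31.76,1012271080
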