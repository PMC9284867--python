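medicine_code,ME_n,ME_pct,MH_n,MH_pct,MD_n,MD_pct,OI_n,OI_pct,total
ANA1,10838515,41.25,8803262,33.5,2913665,11.09,3722340,14.17,26277782
DOC40,12097460,45.5,8352420,31.41,1834800,6.9,4304760,16.19,26589440
EXE25,21923725,48.42,7926800,17.51,8587175,18.96,6842850,15.11,45280550
LET25,2109253,58.52,196850,5.46,1040350,28.86,257963,7.16,3604415
PAC6,60776655,63.34,18113116,18.88,5987234,6.24,11082205,11.55,95959210
TAM20,394563360,54.89,205193800,28.55,26791300,3.73,92260920,12.84,718809382
TRA440,3030720,10.25,7537200,25.49,6787880,22.96,12208240,41.29,29564040
VIN10,2058470,57.79,854040,23.98,233700,6.56,415870,11.67,3562080
VIN20,1047080,40.6,1063520,41.24,428380,16.61,40000,1.55,2578980
VIN30,3007350,56.41,1512930,28.38,750600,14.08,60000,1.13,5330880
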