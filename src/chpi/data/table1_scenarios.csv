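host_id,guest_id,n_walls,substituent,esp_kcal_mol,method,K_M,K_sigma_M
1a,2a,0,,,NMR,72.2,14.0
1b,2a,2,OMe,-20.7,NMR,5150,1300
1c,2a,2,N3,-12.9,NMR,3870,400
1d,2a,2,NO2,-2.0,NMR,4720,900
1e,2a,4,OMe,-20.7,ITC,141000,10000
1f,2a,4,NO2,-2.0,ITC,106000,10000
1a,2b,0,,,NMR,8.91,1.8
1b,2b,2,OMe,-20.7,NMR,82.1,9.0
1c,2b,2,N3,-12.9,NMR,70.0,8.0
1d,2b,2,NO2,-2.0,NMR,79.8,16.0
1e,2b,4,OMe,-20.7,NMR,96.0,9.0
1f,2b,4,NO2,-2.0,NMR,257,30.0
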