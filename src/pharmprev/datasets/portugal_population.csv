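region,year,inhabitants
Aveiro,2018,695702
Aveiro,2021,700957
Beja,2018,141178
Beja,2021,144465
Braga,2018,828650
Braga,2021,846418
Bragança,2018,124571
Bragança,2021,122826
Castelo Branco,2018,179038
Castelo Branco,2021,177995
Coimbra,2018,405267
Coimbra,2021,408609
Évora,2018,152865
Évora,2021,152511
Faro,2018,438864
Faro,2021,467475
Guarda,2018,144354
Guarda,2021,142998
Leiria,2018,454592
Leiria,2021,458672
Lisboa,2018,2271772
Lisboa,2021,2275846
Portalegre,2018,105479
Portalegre,2021,104930
Porto,2018,1778146
Porto,2021,1785627
Santarém,2018,429719
Santarém,2021,425025
Setubal,2018,852328
Setubal,2021,874926
Viana do Castelo,2018,230954
Viana do Castelo,2021,231293
Vila Real,2018,191894
Vila Real,2021,185705
Viseu,2018,354453
Viseu,2021,351315
Madeira,2018,253945
Madeira,2021,250769
Açores,2018,242846
Açores,2021,236440
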