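# National antidiabetic consumption, DDD per 1000 inhabitants per day,
# Portugal 2018 and 2021, by ATC class. Level-3 rows (A10A insulins,
# A10B non-insulin antidiabetics) are the published class totals; the
# level-4 rows are the chemical-subgroup breakdown as published (their
# sums can differ from the class totals in the last decimal), and the
# A10 rows are the published all-antidiabetic totals.
atc_class,year,did
A10AB,2018,2.8
A10AC,2018,1.8
A10AD,2018,4.0
A10AE,2018,7.0
A10A,2018,15.5
A10BA,2018,24.2
A10BB,2018,14.5
A10BD,2018,22.4
A10BF,2018,0.7
A10BG,2018,0.4
A10BH,2018,7.0
A10BJ,2018,1.6
A10BK,2018,4.4
A10BX,2018,0.2
A10B,2018,75.4
A10,2018,91.0
A10AB,2021,3.3
A10AC,2021,1.3
A10AD,2021,3.3
A10AE,2021,8.1
A10A,2021,16.0
A10BA,2021,24.5
A10BB,2021,11.5
A10BD,2021,28.3
A10BF,2021,0.4
A10BG,2021,0.4
A10BH,2021,7.6
A10BJ,2021,4.9
A10BK,2021,11.2
A10BX,2021,0.1
A10B,2021,88.9
A10,2021,104.9
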