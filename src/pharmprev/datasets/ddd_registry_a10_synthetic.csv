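# Synthetic DDD registry for the A10 (antidiabetic) formulary.
# Test/demo scaffolding: quantities are plausible working values declared
# here, NOT an extract of the official WHO ATC/DDD index. IU entries are
# insulins, UD entries are fixed-dose combinations counted in unit doses.
atc,ddd_quantity,ddd_unit,route
A10AB01,40,IU,parenteral
A10AB05,40,IU,parenteral
A10AC01,40,IU,parenteral
A10AD01,40,IU,parenteral
A10AE04,40,IU,parenteral
A10AE06,40,IU,parenteral
A10BA02,2000,mg,oral
A10BB09,60,mg,oral
A10BB12,2,mg,oral
A10BD07,2,UD,oral
A10BD15,2,UD,oral
A10BF01,300,mg,oral
A10BG03,30,mg,oral
A10BH01,100,mg,oral
A10BH02,100,mg,oral
A10BJ02,1.2,mg,parenteral
A10BJ06,0.5,mg,parenteral
A10BK01,10,mg,oral
A10BK03,17.5,mg,oral
A10BX02,4,mg,oral
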