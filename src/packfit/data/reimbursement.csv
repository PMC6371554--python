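substance,strength_value,strength_unit,units_per_package,status
amoxicillin,500,mg,16,current
amoxicillin,1000,mg,16,current
amoxicillin,1000,mg,20,former
co-amoxiclav,1000,mg,12,current
co-amoxiclav,1000,mg,14,current
azithromycin,250,mg,6,current
azithromycin,500,mg,3,current
azithromycin,1000,mg,1,current
cephalexin,500,mg,16,current
cephalexin,1000,mg,16,current
clindamycin,150,mg,16,current
clindamycin,300,mg,16,current
clindamycin,600,mg,16,current
clindamycin,600,mg,32,current
clarithromycin,250,mg,14,current
clarithromycin,500,mg,7,current
clarithromycin,500,mg,14,current
penicillin V,1000000,IU,30,current
penicillin V,1500000,IU,30,current
erythromycin,250,mg,16,current
cefixime,400,mg,5,current
cefixime,400,mg,10,current
cefuroxime,125,mg,10,current
cefuroxime,250,mg,10,current
cefuroxime,500,mg,10,current
cefuroxime,500,mg,14,current
cefuroxime,500,mg,16,current
norfloxacin,400,mg,20,current
ciprofloxacin,250,mg,10,current
ciprofloxacin,500,mg,10,current
fosfomycinum,2000,mg,1,current
fosfomycinum,3000,mg,1,current
fosfomycinum,3000,mg,2,current
levofloxacin,500,mg,10,current
nitrofurantoin,50,mg,30,current
"sulfametoxazole, trimethoprim",120,mg,20,current
"sulfametoxazole, trimethoprim",480,mg,20,current
"sulfametoxazole, trimethoprim",960,mg,20,current
linezolid,600,mg,10,current
moxifloxacin,400,mg,5,current
moxifloxacin,400,mg,7,current
moxifloxacin,400,mg,10,current
telithromycin,400,mg,10,former
telithromycin,400,mg,14,former
telithromycin,400,mg,20,former
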