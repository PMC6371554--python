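trade_name,atc_code,substance,form,strength_value,strength_unit,divisible,package_sizes,marketing_status,dose_prespecified,paediatric
Amoxicillin caps,J01CA04,amoxicillin,capsule,500,mg,false,16;20,marketed,true,false
Amoxicillin 1000 scored,J01CA04,amoxicillin,tablet,1000,mg,true,16,marketed,true,false
Amoxicillin 1000 film,J01CA04,amoxicillin,tablet,1000,mg,false,20,marketed,true,false
Co-amoxiclav 875/125,J01CR02,co-amoxiclav,tablet,1000,mg,false,10;12;14;16;20;21;24;30,marketed,true,false
Azithromycin 125,J01FA10,azithromycin,tablet,125,mg,false,6,marketed,true,false
Azithromycin 250,J01FA10,azithromycin,tablet,250,mg,false,6,marketed,true,false
Azithromycin 500,J01FA10,azithromycin,tablet,500,mg,false,1;2;3;6;12;24,marketed,true,false
Azithromycin 1000,J01FA10,azithromycin,tablet,1000,mg,false,1;2;3;6,marketed,true,false
Cephalexin 500,J01DB01,cephalexin,capsule,500,mg,false,16,marketed,true,false
Cephalexin 1000,J01DB01,cephalexin,capsule,1000,mg,false,16,marketed,true,false
Clindamycin 150,J01FF01,clindamycin,capsule,150,mg,false,16,marketed,true,false
Clindamycin 300,J01FF01,clindamycin,capsule,300,mg,false,16,marketed,true,false
Clindamycin 600,J01FF01,clindamycin,tablet,600,mg,true,16;32,marketed,true,false
Clarithromycin 250,J01FA09,clarithromycin,tablet,250,mg,false,14,marketed,true,false
Clarithromycin 500,J01FA09,clarithromycin,tablet,500,mg,false,5;7;14,marketed,true,false
Penicillin V 1M,J01CE02,penicillin V,tablet,1000000,IU,true,30,marketed,true,false
Penicillin V 1.5M,J01CE02,penicillin V,tablet,1500000,IU,true,30,marketed,true,false
Erythromycin 250,J01FA01,erythromycin,tablet,250,mg,false,16,marketed,true,false
Cefixime 400,J01DD08,cefixime,tablet,400,mg,false,5;10,marketed,true,false
Cefuroxime 125,J01DC02,cefuroxime,tablet,125,mg,false,10,marketed,true,false
Cefuroxime 250,J01DC02,cefuroxime,tablet,250,mg,false,10,marketed,true,false
Cefuroxime 500,J01DC02,cefuroxime,tablet,500,mg,false,8;10;12;14;15;16;20;24,marketed,true,false
Norfloxacin 400,J01MA06,norfloxacin,tablet,400,mg,false,20,marketed,true,false
Ciprofloxacin 250,J01MA02,ciprofloxacin,tablet,250,mg,false,10,marketed,true,false
Ciprofloxacin 500,J01MA02,ciprofloxacin,tablet,500,mg,false,10,marketed,true,false
Fosfomycin 2g granules,J01XX01,fosfomycinum,granules,2000,mg,false,1;2,marketed,true,false
Fosfomycin 3g granules,J01XX01,fosfomycinum,granules,3000,mg,false,1;2,marketed,true,false
Levofloxacin 500,J01MA12,levofloxacin,tablet,500,mg,true,1;5;7;10;14,marketed,true,false
Nitrofurantoin 50,J01XE01,nitrofurantoin,capsule,50,mg,false,30,marketed,true,false
Co-trimoxazole 120,J01EE01,"sulfametoxazole, trimethoprim",tablet,120,mg,false,20,marketed,true,false
Co-trimoxazole 480,J01EE01,"sulfametoxazole, trimethoprim",tablet,480,mg,false,20,marketed,true,false
Co-trimoxazole 960,J01EE01,"sulfametoxazole, trimethoprim",tablet,960,mg,false,20,marketed,true,false
Linezolid 600,J01XX08,linezolid,tablet,600,mg,false,10;20;28;30,marketed,true,false
Moxifloxacin 400,J01MA14,moxifloxacin,tablet,400,mg,false,1;5;7;10;14;25;28;30,marketed,true,false
Telithromycin 400,J01FA15,telithromycin,tablet,400,mg,false,10;14;20,marketed,true,false
Doxycycline 100,J01AA02,doxycycline,capsule,100,mg,false,5;6;25,marketed,true,false
Gentamicin inj,J01GB03,gentamicin,solution for injection,40,mg,false,10,marketed,true,false
Azithromycin oral susp,J01FA10,azithromycin,powder for oral suspension,100,mg,false,1,marketed,false,true
Amoxicillin oral susp,J01CA04,amoxicillin,powder for oral suspension,250,mg,false,1,marketed,false,true
Fluconazole caps,J02AC01,fluconazole,capsule,150,mg,false,1,marketed,true,false
Old amoxicillin brand,J01CA04,amoxicillin,capsule,250,mg,false,16,discontinued,true,false
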