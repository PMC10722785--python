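country,row,sector,measure,adj_lower,adj_upper,voly_lower,voly_upper,vsl_lower,vsl_upper,voq_lower,voq_upper,excluded_cells,note
UK,1,health,VOQ,20000,30000,18399,27599,663351.0,995027.0,20000.0,30000.0,,
UK,2,health,VOQ,50000,50000,45998,45998,1658378.0,3316756.0,50000.0,50000.0,vsl_upper,source prints a range VSL for a point input
UK,3,health,VOQ,100000,300000,91996,275988,3316756.0,9950268.0,100000.0,300000.0,,
UK,4,health,VOQ,60000,60000,55198,55198,1990054.0,1990054.0,60000.0,60000.0,,
UK,5,health,VOQ,70000,70000,64397,64397,2321729.0,2321729.0,70000.0,70000.0,,
UK,6,health,VOQ,15000,15000,13799,13799,497513.0,497513.0,15000.0,15000.0,,
UK,7,transport,VSL,2064189,2064189,67650,67650,2064189.0,2064189.0,73535.0,73535.0,,
UK,8,environment,VOLY,45343,45343,45343,45343,1383543.0,1383543.0,49288.0,49288.0,,
UK,9,environment,VOLY,23435,23435,23435,23435,715068.0,715068.0,25474.0,25474.0,,
UK,10,other,VOLY,60000,60000,60000,60000,1830770.0,1830770.0,65220.0,65220.0,,
NL,1,health,VOQ,20000,20000,18399,18399,671639.0,671639.0,20000.0,20000.0,,
NL,2,health,VOQ,50000,50000,45998,45998,1679098.0,1679098.0,50000.0,50000.0,,
NL,3,health,VOQ,80000,80000,73597,73597,2686557.0,2686557.0,80000.0,80000.0,,
NL,4,transport,VSL,1500000,1500000,48553,48553,1500000.0,1500000.0,52777.0,52777.0,,
NL,5,environment,VSL,2400000,2400000,77685,77685,2400000.0,2400000.0,84443.0,84443.0,,
NL,6,environment,VOLY,74244,74244,74244,74244,2293699.0,2293699.0,80703.0,80703.0,,
NL,7,other,VOQ,50000,100000,45998,91996,1679098.0,3358196.0,50000.0,100000.0,,
NL,8,other,VOQ,70000,70000,64397,64397,2350737.0,2350737.0,70000.0,70000.0,,
CA,1,health,VOQ,50000,50000,45998,45998,1683060.0,1683060.0,50000.0,50000.0,,
CA,2,health,VOQ,100000,100000,91996,91996,3366119.0,3366119.0,100000.0,100000.0,,
CA,3,health,VOQ,140000,140000,128794,128794,4712567.0,4712567.0,140000.0,140000.0,,
CA,4,health,VOQ,60000,60000,55198,55198,2019672.0,2019672.0,60000.0,60000.0,,
CA,5,transport,VSL,8079656,8079656,260912,260912,8079656.0,8079656.0,283612.0,283612.0,,
CA,6,environment,VSL,8079656,8079656,260912,260912,8079656.0,8079656.0,283612.0,283612.0,,
JP,1,health,VOQ,5000000,10000000,4599800,9199600,158701235.0,317402469.0,5000000.0,10000000.0,,
JP,2,health,VOQ,7500000,15000000,6899700,13799400,238051852.0,476103704.0,7500000.0,15000000.0,,
JP,3,transport,VSL,226000000,462000000,7739790,15822049,226000000.0,462000000.0,8413152.0,17198567.0,,
JP,4,environment,VSL,103000000,344000000,3527427,11780920,103000000.0,344000000.0,3834313.0,12805860.0,,
AU,1,health,VOQ,52400,52400,48206,48206,996295.0,996295.0,52400.0,52400.0,,
AU,2,health,VOQ,75000,75000,68997,68997,1425994.0,1425994.0,75000.0,75000.0,,
AU,3,health,VOQ,50000,50000,45998,45998,950663.0,950663.0,50000.0,50000.0,,
AU,4,transport,VSL,3215595,3215595,183838,183838,3215595.0,3215595.0,199832.0,199832.0,,
AU,5,environment,VOLY,288991,288991,288991,288991,5054867.0,5054867.0,314133.0,314133.0,,
AU,6,environment,VSL,6000000,6000000,343025,343025,6000000.0,6000000.0,372868.0,372868.0,,
AU,7,other,VOLY,213000,213000,213000,213000,3725676.0,3725676.0,231531.0,231531.0,,
AU,8,other,VSL,4900000,4900000,280137,280137,4900000.0,4900000.0,304509.0,304509.0,,
NZ,1,health,VOQ,28342,28342,26073,26073,667896.0,667896.0,28341.0,28341.0,vsl_lower;vsl_upper,"source VSL implies adjusted 28,341, contradicting its own 28,342 cell"
NZ,2,health,VOQ,33306,33306,30640,30640,784904.0,784904.0,33306.0,33306.0,,
NZ,3,transport,VSL,4494540,4494540,207311,207311,4494540.0,4494540.0,225347.0,225347.0,,
NZ,4,transport,VSL,4900000,4900000,226013,226013,4900000.0,4900000.0,245676.0,245676.0,,
NZ,5,environment,VSL,4900000,4900000,226013,226013,4900000.0,4900000.0,245676.0,245676.0,,
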