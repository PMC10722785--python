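country,row,sector,source,relevance,measure,stated_lower,stated_upper,stated_year,currency,needs_update,in_comparison_set,is_hta_reference,hta_ref_bound,analysis_excluded
UK,1,health,NICE,Threshold used to assess 'normal' treatments,QALY,20000,30000,2013,GBP,false,false,true,both,false
UK,2,health,NICE,Threshold used to assess 'end-of-life' treatments,QALY,50000,50000,2013,GBP,false,false,false,both,false
UK,3,health,NICE,Threshold used to assess 'highly specialised technologies',QALY,100000,300000,2017,GBP,false,false,false,both,false
UK,4,health,HM Treasury,Health-related appraisal (Green Book),QALY,60000,60000,2018,GBP,false,false,false,both,false
UK,5,health,HM Treasury,Health-related appraisal (Green Book),QALY,70000,70000,2022,GBP,false,false,false,both,true
UK,6,health,DHSC,Adopted in relevant Impact Assessments,QALY,15000,15000,2016,GBP,false,false,false,both,true
UK,7,transport,HM Treasury/DfT,Social cost-benefit analysis (Green Book),VPF,2064189,2064189,2020,GBP,false,true,false,both,false
UK,8,environment,Defra,Valuing life lost due to chronic effects of air pollution,VOLY,42780,42780,2017,GBP,true,true,false,both,false
UK,9,environment,Defra,Valuing life lost due to acute effects of air pollution,VOLY,22110,22110,2017,GBP,true,true,false,both,false
UK,10,other,HM Treasury,Social cost-benefit analysis (Green Book),SLY,60000,60000,2018,GBP,false,false,false,both,false
NL,1,health,ZIN,Treatments with proportional QALY shortfall of 0.10-0.40,QALY,20000,20000,2015,EUR,false,false,true,both,false
NL,2,health,ZIN,Treatments with proportional QALY shortfall of 0.41-0.70,QALY,50000,50000,2015,EUR,false,false,false,both,false
NL,3,health,ZIN,Treatments with proportional QALY shortfall of 0.71-1.00,QALY,80000,80000,2015,EUR,false,false,false,both,false
NL,4,transport,OEEI Guideline,Values for transport infrastructure projects: European average from an OECD publication,VPF,1500000,1500000,1998,EUR,false,true,false,both,false
NL,5,environment,CE Delft,Valuing life lost due to air pollution (though VOLY is preferred),VSL,2400000,2400000,2012,EUR,false,false,false,both,false
NL,6,environment,CE Delft,Valuing the health impact of environmental pollution,VOLY,70000,70000,2015,EUR,true,true,false,both,false
NL,7,other,SEO,Values for social cost-benefit analysis in the social domain,QALY,50000,100000,2015,EUR,false,false,false,both,false
NL,8,other,CE Delft,Central estimate of the range for social cost-benefit analysis in the social domain,QALY,70000,70000,2015,EUR,false,false,false,both,false
CA,1,health,PMPRB,Estimate of the lower bound of the QALY threshold range,QALY,50000,50000,2019,CAD,false,false,true,both,false
CA,2,health,PMPRB,Estimate of the upper bound of the QALY threshold range (oncology drugs),QALY,100000,100000,2019,CAD,false,false,true,both,false
CA,3,health,Skedgel et al,Academic estimate of an implied threshold for pCODR (oncology drugs),QALY,140000,140000,2018,CAD,false,false,false,both,false
CA,4,health,PMPRB,Proposed future threshold value,QALY,60000,60000,2020,CAD,false,false,false,both,false
CA,5,transport,TBS,Estimate for use in cost-benefit analysis,VSL,6110000,6110000,2004,CAD,true,true,false,both,false
CA,6,environment,TBS,Estimate for use in cost-benefit analysis,VSL,6110000,6110000,2004,CAD,true,true,false,both,false
JP,1,health,MHLW,Price adjustment threshold for 'normal' treatments,QALY,5000000,10000000,2019,JPY,false,false,true,lower,false
JP,2,health,MHLW,Price adjustment threshold for products with 'special considerations',QALY,7500000,15000000,2019,JPY,false,false,false,both,false
JP,3,transport,Cabinet Office,Estimates in relation to road accidents (Morisugi et al),VSL,226000000,462000000,2007,JPY,false,true,false,both,false
JP,4,environment,Itaoka et al,Estimates in relation to air pollution,VSL,103000000,344000000,1999,JPY,false,true,false,both,false
AU,1,health,"Henry, Hill & Harris",Estimate based on PBAC decisions between 1994-2003,QALY,52400,52400,2003,AUD,false,false,true,both,false
AU,2,health,Paris & Belloni,Estimate of maximum cut-off based on PBAC decisions between 2005-2009,QALY,75000,75000,2009,AUD,false,false,true,both,false
AU,3,health,"Wang, Gum & Merlin",Threshold used to compare PBAC and NICE decisions 2005-2015,QALY,50000,50000,2015,AUD,false,false,false,both,false
AU,4,transport,BITRE,Estimate of the cost per road fatality,VSL,2400000,2400000,2006,AUD,true,true,false,both,false
AU,5,environment,NEPC/Boulter & Kulkarni,Economic analysis to inform the National Plan for Clean Air,VOLY,288991,288991,2011,AUD,false,true,false,both,false
AU,6,environment,NEPC/Boulter & Kulkarni,Economic analysis to inform the National Plan for Clean Air,VSL,6000000,6000000,2006,AUD,false,false,false,both,false
AU,7,other,PM&C,For use in cost-benefit analyses for regulation impact statements,VOLY,213000,213000,2019,AUD,false,false,false,both,false
AU,8,other,PM&C,For use in cost-benefit analyses for regulation impact statements,VSL,4900000,4900000,2019,AUD,false,false,false,both,false
NZ,1,health,Pritchard et al,Academic estimate based on PHARMAC decisions from 1998-2001,QALY,20000,20000,2001,NZD,true,false,false,both,false
NZ,2,health,Treasury,Value from the CBAx tool for use in cost benefit analysis,QALY,33306,33306,2019,NZD,false,false,true,both,false
NZ,3,transport,Ministry of Transport,Estimate in the context of road crashes and injuries,VSL,4340000,4340000,2018,NZD,true,false,false,both,false
NZ,4,transport,Treasury,Value from the CBAx tool for use in cost benefit analysis,VSL,4900000,4900000,2019,NZD,false,true,false,both,false
NZ,5,environment,Treasury,Value from the CBAx tool for use in cost benefit analysis,VSL,4900000,4900000,2019,NZD,false,true,false,both,false
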