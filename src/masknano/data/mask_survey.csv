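mask_id,mask_type,layer_id,position,composition,fiber_class,d_f_um,d_f_iqr_um,contains_tio2,d_a_nm,d_a_iqr_nm,d_cp_nm,d_cp_iqr_nm,perimeter_ratio,layer_mass_ug,m_tot_ug,m_tot_u_ug,printed_fraction_pct,printed_m_sf_ug,printed_exceedance
Mask01,single_use,external,external,Thermobonded non-woven,nonwoven_thermobonded,24,7.4,true,197,59,131,61,1,NA,2386,286,2,39,11
Mask01,single_use,central,central,Meltblown non-woven,nonwoven_meltblown,NA,NA,false,NA,NA,NA,NA,1,NA,2386,286,NA,39,11
Mask01,single_use,internal,internal,Thermobonded non-woven,nonwoven_thermobonded,NA,NA,false,NA,NA,NA,NA,1,NA,2386,286,NA,39,11
Mask02,reusable,external,external,Polyester,cylindrical_synthetic,9,0.7,true,123,76,125,72,1,NA,17332,2080,3,462,128
Mask02,reusable,central,central,Meltblown non-woven,nonwoven_meltblown,NA,NA,false,NA,NA,NA,NA,1,NA,17332,2080,NA,462,128
Mask02,reusable,internal,internal,100% cotton,cotton,NA,NA,false,NA,NA,NA,NA,1,NA,17332,2080,NA,462,128
Mask03,reusable,external,external,100% polyester,cylindrical_synthetic,9,0.9,true,188,121,124,48,1,NA,30757,3691,4,1056,293
Mask03,reusable,central,central,"65% polyester, 35% cotton",cylindrical_synthetic,11,0.7,true,156,104,107,59,1,NA,30757,3691,3,1056,293
Mask03,reusable,internal,internal,"65% polyester, 35% cotton",cylindrical_synthetic,11,2.0,true,173,101,133,45,1,NA,30757,3691,3,1056,293
Mask04,single_use,external,external,Thermobonded non-woven,nonwoven_thermobonded,21,1.8,true,220,66,182,80,1,NA,1370,164,2,30,8
Mask04,single_use,central,central,Meltblown non-woven,nonwoven_meltblown,NA,NA,false,NA,NA,NA,NA,1,NA,1370,164,NA,30,8
Mask04,single_use,internal,internal,Thermobonded non-woven,nonwoven_thermobonded,23,7.2,true,274,76,143,97,1,NA,1370,164,2,30,8
Mask05,single_use,external,external,Thermobonded non-woven,nonwoven_thermobonded,19,2.5,true,233,107,184,74,1,NA,791,95,2,17,5
Mask05,single_use,central,central,Meltblown non-woven,nonwoven_meltblown,NA,NA,false,NA,NA,NA,NA,1,NA,791,95,NA,17,5
Mask05,single_use,internal,internal,Thermobonded non-woven,nonwoven_thermobonded,18,2.8,true,171,82,168,58,1,NA,791,95,2,17,5
Mask06,reusable,external,external,Polyester,cylindrical_synthetic,7,0.4,true,147,57,101,46,1,NA,12195,1463,4,448,87
Mask06,reusable,central,central,Unknown,unknown,35,8.4,true,409,182,117,32,1,NA,12195,1463,2,448,87
Mask06,reusable,internal,internal,Cotton,cotton,NA,NA,false,NA,NA,NA,NA,1,NA,12195,1463,NA,448,87
Mask07,reusable,external,external,Polyamide,cylindrical_synthetic,9,1.2,true,130,98,96,38,1,NA,152345,18281,3,4394,1220
Mask07,reusable,internal,internal,Polyamide,cylindrical_synthetic,9,0.7,true,135,118,103,44,1,NA,152345,18281,3,4394,1220
Mask08,reusable,whole,whole-mask,"Polyester, polyamide, elastane",cylindrical_synthetic,11,1.0,true,184,87,99,50,1,NA,9573,1149,3,327,136
Mask09,reusable,external,external,Thermobonded non-woven,nonwoven_thermobonded,24,6.5,true,450,130,147,73,1,NA,2298,276,4,84,16
Mask09,reusable,central,central,Meltblown non-woven,nonwoven_meltblown,NA,NA,false,NA,NA,NA,NA,1,NA,2298,276,NA,84,16
Mask09,reusable,internal,internal,Thermobonded non-woven,nonwoven_thermobonded,23,6.4,true,372,177,157,56,1,NA,2298,276,3,84,16
Mask10,reusable,external,external,Polyester,cylindrical_synthetic,11,0.8,true,110,84,90,40,1,NA,17427,2091,2,358,99
Mask10,reusable,internal,internal,Cotton,cotton,NA,NA,false,NA,NA,NA,NA,1,NA,17427,2091,NA,358,99
Mask11,reusable,external,external,Polyester,cylindrical_synthetic,10,0.6,true,135,69,89,32,1,NA,12713,1526,3,352,98
Mask11,reusable,central,central,Thermobonded non-woven,nonwoven_thermobonded,NA,NA,false,NA,NA,NA,NA,1,NA,12713,1526,NA,352,98
Mask11,reusable,internal,internal,Cotton,cotton,NA,NA,false,NA,NA,NA,NA,1,NA,12713,1526,NA,352,98
Mask12,reusable,external,external,Bi-component microfiber,bicomponent,13,0.8,true,173,95,105,45,3.0,NA,12929,1552,8,1054,293
Mask12,reusable,internal,internal,Bi-component microfiber,bicomponent,12,1.7,true,191,104,96,43,3.0,NA,12929,1552,9,1054,293
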