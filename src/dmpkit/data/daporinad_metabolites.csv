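label,transformation,mz,formula_printed,formula,rt_min,steps,amine_steps,acyl_steps,n_oxide,mouse_liver_microsome,human_liver_microsome,mouse_plasma,note
M1,Amide hydrolysis,261.1961,C16H24N2O4,C16H24N2O,7.36,amide_hydrolysis=1,,,no,O,O,O,printed formula inconsistent with printed m/z and transformation; corrected to match both
M2,Desaturation + Oxidation,406.2125,C24H27N3O3,C24H27N3O3,10.07,desaturation=1;oxidation=1,desaturation=1;oxidation=1,,no,-,-,O,
M3,Di-desaturation,388.2020,C24H31N3O2,C24H25N3O2,11.53,desaturation=2,desaturation=2,,no,O,O,O,printed formula inconsistent with printed m/z and transformation; corrected to match both
M4,Oxidation,408.2282,C24H29N3O3,C24H29N3O3,11.99,oxidation=1,oxidation=1,,no,O,O,O,
M5,Di-oxidation,424.2231,C24H29N3O4,C24H29N3O4,12.48,oxidation=2,oxidation=2,,no,O,-,O,
M6,Di-oxidation,424.2231,C24H29N3O4,C24H29N3O4,13.46,oxidation=2,oxidation=1,oxidation=1,yes,-,-,O,
M7,Di-oxidation,424.2231,C24H29N3O4,C24H29N3O4,13.91,oxidation=2,oxidation=1,oxidation=1,no,-,-,O,
M8,Oxidation,408.2282,C24H29N3O3,C24H29N3O3,14.00,oxidation=1,oxidation=1,,no,O,O,O,
M9,Di-desaturation,388.2020,C24H31N3O2,C24H25N3O2,14.11,desaturation=2,desaturation=2,,no,O,O,O,printed formula inconsistent with printed m/z and transformation; corrected to match both
M10,Di-oxidation,424.2231,C24H29N3O4,C24H29N3O4,14.29,oxidation=2,oxidation=1,oxidation=1,yes,-,-,O,
M11,Tri-oxidation,440.2180,C24H29N3O5,C24H29N3O5,14.41,oxidation=3,oxidation=2,oxidation=1,yes,O,-,O,
M12,Saturation,394.2489,C24H31N3O2,C24H31N3O2,15.37,saturation=1,,saturation=1,no,-,-,O,
M13,Di-oxidation,424.2231,C24H29N3O4,C24H29N3O4,15.87,oxidation=2,oxidation=1,oxidation=1,no,-,-,O,
M14,Desaturation + Oxidation,406.2125,C24H27N3O3,C24H27N3O3,16.04,desaturation=1;oxidation=1,desaturation=1;oxidation=1,,no,-,-,O,
M15,Tri-oxidation,440.2180,C24H29N3O5,C24H29N3O5,16.54,oxidation=3,oxidation=2,oxidation=1,no,-,-,O,
M16,Desaturation,390.2176,C24H27N3O2,C24H27N3O2,17.27,desaturation=1,desaturation=1,,no,O,O,O,
M17,Oxidation,408.2282,C24H29N3O3,C24H29N3O3,17.76,oxidation=1,oxidation=1,,no,O,O,O,
M18,Desaturation + Oxidation,406.2125,C24H27N3O3,C24H27N3O3,19.15,desaturation=1;oxidation=1,desaturation=1,oxidation=1,yes,O,-,O,
M19,Desaturation + Oxidation,406.2125,C24H27N3O3,C24H27N3O3,21.02,desaturation=1;oxidation=1,desaturation=1,oxidation=1,no,-,-,O,
M20,Amide hydrolysis followed by carboxylation,276.1594,C16H21NO3,C16H21NO3,21.25,hydrolysis_then_carboxylation=1,,,no,O,O,O,
Parent,Parent,392.2333,C24H29N3O2,C24H29N3O2,22.31,,,,untested,O,O,O,
M21,Amide hydrolysis followed by hydroxylation,262.1802,C16H23NO2,C16H23NO2,22.76,hydrolysis_then_hydroxylation=1,,,no,O,O,O,
M22,Oxidation,408.2282,C24H29N3O3,C24H29N3O3,24.04,oxidation=1,,oxidation=1,yes,O,O,O,
M23,Desaturation,390.2176,C24H27N3O2,C24H27N3O2,24.67,desaturation=1,desaturation=1,,no,O,O,O,
M24,Oxidation,408.2282,C24H29N3O3,C24H29N3O3,25.90,oxidation=1,,oxidation=1,no,O,-,O,
M25,Desaturation + Oxidation,406.2125,C24H27N3O3,C24H27N3O3,26.31,desaturation=1;oxidation=1,desaturation=1,oxidation=1,yes,O,-,O,
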