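CVX Code	CVX Short Description	Full Vaccine Name	Status	VO Code	Note
93	RSV-MAb	respiratory syncytial virus monoclonal antibody (palivizumab), intramuscular	Active	VO_0006048
145	RSV-MAb (new)	respiratory syncytial virus monoclonal antibody (motavizumab), intramuscular	Inactive	VO_0006047
181	anthrax immune globulin	anthrax immune globulin	Active	VO_0005440
27	botulinum antitoxin	botulinum antitoxin	Active	VO_0006001
29	CMVIG	cytomegalovirus immune globulin, intravenous	Active	VO_0005441
12	diphtheria antitoxin	diphtheria antitoxin	Active	VO_0006005
154	HepA IG	Hepatitis A immune globulin	Active	VO_0005442
30	HBIG	hepatitis B immune globulin	Active	VO_0005443
86	IG	immune globulin, intramuscular	Active	VO_0005444
87	IGIV	immune globulin, intravenous	Active	VO_0005445
14	IG, unspecified	immune globulin, unspecified formulation	Active	VO_0005446
34	RIG	rabies immune globulin	Active	VO_0005447
71	RSV-IGIV	respiratory syncytial virus immune globulin, intravenous	Active	VO_0005448
306	RSV-MAb nirsevimab 0.5 mL	Respiratory syncytial virus (RSV) monoclonal antibody, IgG1k, (nirsevimab-alip), 0.5 mL, neonates and children to 24 months	Active	VO_0010137
307	RSV-MAb nirsevimab 1 mL	Respiratory syncytial virus (RSV) monoclonal antibody, IgG1k, (nirsevimab-alip), 1 mL, neonates and children to 24 months	Active	VO_0010138
315	RSV-MAb unspecified	Respiratory syncytial virus (RSV) monoclonal antibody (MAB), unspecified	Active	VO_0010216
157	Rho(D) IG IM	Rho(D) Immune globulin - IM	Active	VO_0005449
156	Rho(D) IG IV or IM	Rho(D) Immune globulin- IV or IM	Active	VO_0005450
159	Rho(D) unspecified	Rho(D) Unspecified formulation	Active	VO_0005451
13	TIG	tetanus immune globulin	Active	VO_0005452
79	vaccinia immune globulin	vaccinia immune globulin	Active	VO_0005453
36	VZIG	varicella zoster immune globulin	Active	VO_0005454
117	VZIG (IND)	varicella zoster immune globulin (Investigational New Drug)	Active	VO_0005455
180	TIG (duplicate code)	tetanus immune globulin	Inactive	VO_0005452	duplicate of code 13; CDC recommends not using 180
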