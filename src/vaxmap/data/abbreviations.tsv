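# Default vaccine abbreviation / trade-name expansion table.
# Two tab-separated columns: key<TAB>expansion. Keys are matched
# case-insensitively against whole tokens (including slash-separated
# segments such as DTaP/IPV/HepB). Expansions must not themselves
# contain a key as a whole token, so a single expansion pass is
# idempotent. The table is data: extend or replace it freely.
dtap	diphtheria tetanus acellular pertussis
dtp	diphtheria tetanus pertussis
dt	diphtheria tetanus pediatric
td	tetanus diphtheria
tdap	tetanus diphtheria acellular pertussis
ipv	inactivated poliovirus
opv	oral poliovirus
hepb	hepatitis b
hepa	hepatitis a
hib	haemophilus influenzae type b
mmr	measles mumps rubella
mmrv	measles mumps rubella varicella
hpv	human papillomavirus
rsv	respiratory syncytial virus
pcv	pneumococcal conjugate
ppsv	pneumococcal polysaccharide
mcv	meningococcal conjugate
bcg	bacillus calmette guerin
je	japanese encephalitis
vzig	varicella zoster immune globulin
hbig	hepatitis b immune globulin
ig	immune globulin
igiv	immune globulin intravenous
mab	monoclonal antibody
lnp	lipid nanoparticle
pf	preservative free
mdck	madin darby canine kidney
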