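# toy respiratory lexicon: term <TAB> concept id
heart	C0018787
copd	C0024117
chronic obstructive pulmonary disease	C0024117
emphysema	C0034067
chronic bronchitis	C0008677
bronchitis	C0006277
dyspnea	C0013404
shortness of breath	C0013404
wheezing	C0043144
wheeze	C0043144
cough	C0010200
productive cough	C0239134
sputum	C0038056
hypoxia	C0242184
hypoxemia	C0700292
cyanosis	C0010520
bronchodilator	C0006280
albuterol	C0001927
tiotropium	C1274235
ipratropium	C0027235
inhaler	C0021461
nebulizer	C0027524
spirometry	C0037981
fev1	C0849974
oxygen therapy	C0184633
supplemental oxygen	C0184633
respiratory failure	C1145670
exacerbation	C4086268
copd exacerbation	C0740304
smoking	C0037369
tobacco use	C0543414
pack years	C1277691
barrel chest	C0264491
accessory muscle use	C0425468
pursed lip breathing	C0425491
crackles	C0034642
rales	C0034642
rhonchi	C0035508
pulmonary rehabilitation	C0199521
steroid taper	C0149783
prednisone	C0032952
pneumonia	C0032285
asthma	C0004096
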