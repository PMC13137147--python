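name,formula,class
Lactate,C3H6O3,metabolite
Pyruvate,C3H4O3,metabolite
Succinate,C4H6O4,metabolite
Fumarate,C4H4O4,metabolite
Malate,C4H6O5,metabolite
Citrate,C6H8O7,metabolite
alpha-Ketoglutarate,C5H6O5,metabolite
Glucose,C6H12O6,metabolite
Glucose-6-phosphate,C6H13O9P,metabolite
"Fructose-1,6-bisphosphate",C6H14O12P2,metabolite
Glycerol-3-phosphate,C3H9O6P,metabolite
Phosphoenolpyruvate,C3H5O6P,metabolite
Taurine,C2H7NO3S,metabolite
Glutamate,C5H9NO4,metabolite
Glutamine,C5H10N2O3,metabolite
Aspartate,C4H7NO4,metabolite
Alanine,C3H7NO2,metabolite
Serine,C3H7NO3,metabolite
Glycine,C2H5NO2,metabolite
Creatine,C4H9N3O2,metabolite
Creatinine,C4H7N3O,metabolite
Hypoxanthine,C5H4N4O,metabolite
Xanthine,C5H4N4O2,metabolite
Uric acid,C5H4N4O3,metabolite
Inosine,C10H12N4O5,metabolite
Adenosine,C10H13N5O4,metabolite
AMP,C10H14N5O7P,metabolite
ADP,C10H15N5O10P2,metabolite
ATP,C10H16N5O13P3,metabolite
UMP,C9H13N2O9P,metabolite
UDP-glucose,C15H24N2O17P2,metabolite
NAD,C21H27N7O14P2,metabolite
Glutathione,C10H17N3O6S,metabolite
Glutathione disulfide,C20H32N6O12S2,metabolite
Ascorbate,C6H8O6,metabolite
Pantothenate,C9H17NO5,metabolite
N-Acetylaspartate,C6H9NO5,metabolite
Carnitine,C7H15NO3,metabolite
Choline,C5H13NO,metabolite
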