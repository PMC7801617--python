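mutation	recurrence	tissue	histology
P229L	2	Skin	Carcinoma
I392N	1	Pancreas	Carcinoma
V577D	1	Liver	Carcinoma
A893E	3	Central nervous system/pituitary	Glioma/Craniopharyngioma
R1368W	2	Hematopoietic and lymphoid tissue/large intestine	Lymphoid neoplasm/carcinoma
Y1389C	2	Liver	Carcinoma
L1539P	1	Liver	Carcinoma
S1750F	1	Skin	Malignant melanoma
E1770Q	1	Breast	Carcinoma
D2086V	1	Breast	Carcinoma
L2509P	1	Large intestine	Carcinoma
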