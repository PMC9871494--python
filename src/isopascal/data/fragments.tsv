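# Default fragment registry: TMS/MEOX-derivative ions monitored for carbon
# isotopologue distribution analysis of organic and amino acids by GC-MS.
# skeleton = dash-separated backbone carbon positions retained by the ion.
# Valine_2TMS_C1C2: ion formula corrected to the derivative-minus-loss
# arithmetic (C11H27NO2Si2 - C3H7 = C8H20NO2Si2, m/z 218).
name	metabolite	derivative	ion_formula	nominal_mz	skeleton	note
Citrate_4TMS_C1C6	Citrate	4TMS	C17H37O7Si4	465	1-2-3-4-5-6
Citrate_4TMS_C1C5	Citrate	4TMS	C11H21O4Si2	273	1-2-3-4-5
Fumarate_2TMS_C1C4	Fumarate	2TMS	C9H17O4Si2	245	1-2-3-4
Malate_3TMS_C1C4	Malate	3TMS	C12H27O5Si3	335	1-2-3-4
Malate_3TMS_C2C4	Malate	3TMS	C9H21O3Si2	233	2-3-4
Pyruvate_MEOXTMS_C1C3	Pyruvate	MEOX,TMS	C6H12NO3Si	174	1-2-3
Succinate_2TMS_C1C4	Succinate	2TMS	C9H19O4Si2	247	1-2-3-4
Asparagine_2TMS_C2C4	Asparagine	2TMS	C6H15N2OSi	159	2-3-4
Asparagine_3TMS_C2C4	Asparagine	3TMS	C9H23N2OSi2	231	2-3-4
Aspartate_2TMS_C2C4	Aspartate	2TMS	C6H14NO2Si	160	2-3-4
Aspartate_3TMS_C2C4	Aspartate	3TMS	C9H22NO2Si2	232	2-3-4
Glutamate_3TMS_C2C5	Glutamate	3TMS	C10H24NO2Si2	246	2-3-4-5
Glutamine_3TMS_C2C5	Glutamine	3TMS	C10H25N2OSi2	245	2-3-4-5
Glycine_3TMS_C2	Glycine	3TMS	C7H20NSi2	174	2
Isoleucine_2TMS_C2C6	Isoleucine	2TMS	C8H20NSi	158	2-3-4-5-6
Leucine_2TMS_C2C6	Leucine	2TMS	C8H20NSi	158	2-3-4-5-6
Lysine_4TMS_C2C6	Lysine	4TMS	C14H37N2Si3	317	2-3-4-5-6
Methionine_2TMS_C2C5	Methionine	2TMS	C7H18NSSi	176	2-3-4-5
Ornithine_4TMS_C1C5	Ornithine	4TMS	C17H44N2O2Si4	420	1-2-3-4-5	molecular_ion
Phenylalanine_2TMS_C2C9	Phenylalanine	2TMS	C11H18NSi	192	2-3-4-5-6-7-8-9
Phenylalanine_2TMS_C1C2	Phenylalanine	2TMS	C8H20NO2Si2	218	1-2
Proline_2TMS_C2C5	Proline	2TMS	C7H16NSi	142	2-3-4-5
Serine_2TMS_C2C3	Serine	2TMS	C5H14NOSi	132	2-3
Serine_3TMS_C2C3	Serine	3TMS	C8H22NOSi2	204	2-3
Serine_3TMS_C1C2	Serine	3TMS	C8H20NO2Si2	218	1-2
Threonine_3TMS_C2C4	Threonine	3TMS	C9H24NOSi2	218	2-3-4
Tryptophan_2TMS_C3C11	Tryptophan	2TMS	C9H8N	130	3-4-5-6-7-8-9-10-11
Tryptophan_2TMS_C1C2	Tryptophan	2TMS	C8H20NO2Si2	218	1-2
Tryptophan_3TMS_C3C11	Tryptophan	3TMS	C12H16NSi	202	3-4-5-6-7-8-9-10-11
Tryptophan_3TMS_C1C2	Tryptophan	3TMS	C8H20NO2Si2	218	1-2
Tyrosine_3TMS_C1C2	Tyrosine	3TMS	C8H20NO2Si2	218	1-2
Tyrosine_3TMS_C2C9	Tyrosine	3TMS	C14H26NOSi2	280	2-3-4-5-6-7-8-9
Valine_2TMS_C2C5	Valine	2TMS	C7H18NSi	144	2-3-4-5
Valine_2TMS_C1C2	Valine	2TMS	C8H20NO2Si2	218	1-2	formula_corrected
AlphaAlanine_2TMS_C2C3	AlphaAlanine	2TMS	C5H14NSi	116	2-3
BetaAlanine_3TMS_C1C3	BetaAlanine	3TMS	C11H28NO2Si3	290	1-2-3
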