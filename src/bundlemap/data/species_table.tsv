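order	species	eye_axial_mm	retinal_gc_millions	acuity_cpd	body_mass_kg	v1_area_mm2	v1_neurons_millions	interbundle_um	density_orthogonal_mm2	density_tangential_mm2	printed_total_low	printed_total_high	printed_neurons_per_column
Artiodactyla	Sus scrofa	24.8	0.584	9.92	182	300	30	78.8	205	NA	61500	NA	490
Eulipotyphla	Erinaceus europaeus	7.2	NA	1.5	0.77	15	1.5	46.4	591	NA	8665	NA	166
Carnivora	Mustela putorius	7.5	0.085	3.57	0.83	78	7.8	26.8	1773	NA	138294	NA	57
Rodentia	Mus musculus	5.28	0.05	0.5	0.03	2.5	0.25	17	4406	NA	11015	NA	23
Rodentia	Rattus norvegicus	5.58	0.086	1.6	0.29	7.1	0.71	27	1929	NA	13696	NA	57
Rodentia	Cavia porcellus	8.7	0.159	2.7	0.57	13.5	1.35	31.5	1283	643	17320	NA	78
Primate	Macaca mulatta	20	1.6	53.6	9.25	1269	3084	23	2318	NA	2941542	NA	101
Primate	Gorilla gorilla	22.5	NA	60	207	1350	3375	28.5	1568	1287	1737450	2116800	184
Primate	Pan troglodytes	20.9	NA	64.28	49.2	1570	4380	27	1746	1243	1951510	2741220	172
Primate	Homo sapiens	24.5	1	64	72	2300	5957	33.5	1135	368	846400	2610500	222
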