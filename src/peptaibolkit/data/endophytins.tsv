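name	compound_number	printed_mz	printed_ppm	printed_formula	aa1	aa2	aa3	aa4	aa5	aa6
Endophytin A1	1	1394.8370	-0.07	C63H111N17O18	Ala	Aib	Lxx	Ala	Gln	Lxxol
Endophytin A2	2	1394.8322	-3.51	C63H111N17O18	Aib	Aib	Vxx	Ala	Gln	Lxxol
Endophytin A3	5	1408.8505	1.56	C64H113N17O18	Aib	Aib	Vxx	Aib	Gln	Lxxol
Endophytin A4	7	1408.8424	1.06	C64H113N17O18	Aib	Vxx	Vxx	Ala	Gln	Lxxol
Endophytin A5	8	1422.8657	1.89	C65H115N17O18	Aib	Aib	Lxx	Aib	Gln	Lxxol
Endophytin A6	12	1422.8665	1.56	C64H112N16O19	Vxx	Aib	Vxx	Ala	Gln	Lxxol
Endophytin A7	11	1409.8345	1.33	C65H115N17O18	Aib	Aib	Vxx	Aib	Glu	Lxxol
Endophytin A8	14	1436.8805	2.43	C66H117N17O18	Aib	Vxx	Lxx	Aib	Gln	Lxxol
Endophytin A9	22	1436.8827	8.28	C65H114N16O19	Vxx	Vxx	Lxx	Ala	Gln	Lxxol
Endophytin A10	15	1423.8642	0.07	C65H114N16O19	Vxx	Vxx	Vxx	Ala	Glu	Lxxol
Endophytin A11	19	1423.8525	0.90	C66H117N17O18	Aib	Vxx	Vxx	Aib	Glu	Lxxol
Endophytin A12	23	1450.8867	-1.51	C67H119N17O18	Vxx	Vxx	Lxx	Aib	Gln	Lxxol
Endophytin A13	24	1437.8672	0.55	C66H116N16O19	Vxx	Aib	Lxx	Aib	Glu	Lxxol
Endophytin B1	25	1484.8862	1.48	C70H117N17O18	Vxx	Vxx	Lxx	Aib	Gln	Pheol
Endophytin B2	26	1471.8369	3.05	C69H114N16O19	Vxx	Aib	Lxx	Aib	Glu	Pheol
Endophytin B3	6	1442.8390	6.72	C67H111N17O18	Aib	Aib	Vxx	Aib	Gln	Pheol
Endophytin B4	10	1456.8501	1.78	C68H113N17O18	Aib	Aib	Lxx	Aib	Gln	Pheol
Endophytin B5	18	1456.8505	2.37	C69H115N17O18	Vxx	Vxx	Vxx	Ala	Gln	Pheol
Endophytin B6	17	1470.8676	-1.51	C68H113N17O18	Aib	Vxx	Vxx	Aib	Gln	Pheol
Endophytin B7	20	1470.8673	0.74	C69H115N17O18	Vxx	Vxx	Vxx	Aib	Gln	Pheol
Endophytin B8	27	1485.8639	-2.75	C70H116N16O19	Vxx	Vxx	Lxx	Aib	Glu	Pheol
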