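kind	code	formula	members
residue	Gly	C2H3NO	Gly
residue	Ala	C3H5NO	Ala
residue	Aib	C4H7NO	Aib
residue	Ser	C3H5NO2	Ser
residue	Pro	C5H7NO	Pro
residue	Vxx	C5H9NO	Val,Iva
residue	Lxx	C6H11NO	Leu,Ile
residue	Gln	C5H8N2O2	Gln
residue	Glu	C5H7NO3	Glu
amino_alcohol	Lxxol	C6H15NO	Leucinol,Isoleucinol
amino_alcohol	Pheol	C9H13NO	Phenylalaninol
amino_alcohol	Vxxol	C5H13NO	Valinol,Isovalinol
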