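species	location	abbreviation	n	region
Bostockia porosa	Hill River	BpoHR	2	W
Bostockia porosa	Canebrake Pool	BpoCBP	1	W
Nannatherina balstoni	Inlet River	NbalIR	2	W
Nannoperca variegata	Glenelg River	NvaGR	2	E
Nannoperca variegata	Ewen Ponds	NvaEP	2	E
Nannoperca vittata sp. 1	Arrowsmith River	NviAR	2	W
Nannoperca vittata sp. 2	Doggerup Creek	NviDC	2	W
Nannoperca vittata sp. 3	Canebreak Pool	NviCBP	2	W
Nannoperca pygmaea	Mitchell River	NpyMR	2	W
Nannoperca oxleyana	Stradbroke Island	NoxSI	4	E
Nannoperca obscura	Gnarkeet Creek	NobGC	2	E
Nannoperca obscura	Shaw River	NobSR	2	E
Nannoperca obscura	Tookyaerta breeders	NobTBR	2	E
Nannoperca obscura	Mosquito Creek	NobMC	2	E
Nannoperca australis	Darby River	NauDR	2	E
Nannoperca australis	Gellibrand River	NauGRF	1	E
Nannoperca australis	Mundy Gully	NauMG	1	E
Nannoperca australis	Curdies River	NauCR	1	E
Nannoperca australis	Swanpool Creek	NauSPC	1	E
Nannoperca australis	Blakney Creek	NauBC	2	E
Nannoperca australis	Meadows Creek	NauMCr	2	E
Nannoperca flindersi	Snowy River	NflSRLO	2	E
Nannoperca flindersi	Anson River	NflAR	2	E
Nannoperca flindersi	Flinders Island	NflFI	2	E
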