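taxon_no	local_name	family	species	endemic	conservation_status
1	Abgaw	Lamiaceae	Premna odorata		LC
2	Alibangbang (puti)	Fabaceae	Phanera semibifida		
3	Alibangbang (tapol)	Fabaceae	Phanera semibifida		
4	Awoy	Lamiaceae	Callicarpa pedunculata		LC
5	Balete	Moraceae	Ficus concinna		LC
6	Banag	Dioscoreaceae	Stenomeris borneensis		
7	Banitlong	Byttneriaceae	Melochia umbellata		
8	Banti (puti)	Euphorbiaceae	Omalanthus macradenius	EN	
9	Banti (tapol)	Euphorbiaceae	Omalanthus macradenius	EN	
10	Gapas-gapas (bae)	Asteraceae	Erechtites valerianifolius		
11	Kaningag	Lauraceae	Cinnamomum mercadoi	EN	VU
12	Kawilan	Rubiaceae	Uncaria lanosa		
13	Lunas-bagon (puti)	Piperaceae	Piper nigrum		
14	Mayana Kanapkap	Lamiaceae	Coleus scutellarioides		
15	Mayana Pula	Lamiaceae	Coleus scutellarioides		
16	Salimbagat	Aristolochiaceae	Thottea affinis	EN	
17	Talimughat 1 (lingin)	Sparmanniaceae	Grewia laevigata		LC
18	Talimughat 2 (taas)	Annonaceae	Friesodielsia lanceolata	EN	
19	Talimughat 3 (pikas)	Fabaceae	Bauhinia sp.		
20	Tobog (puti)	Moraceae	Ficus fistulosa		LC
21	Tobog (tapol)	Moraceae	Ficus cassidyana	EN	
22	Tuba-tuba (puti)	Euphorbiaceae	Jatropha curcas		
23	Tuba-tuba (tapol)	Euphorbiaceae	Jatropha gossypifolia		
24	Tuwa-tuwa	Asteraceae	Ficus sp.		
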