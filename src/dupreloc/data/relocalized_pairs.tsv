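gene1	scl1	gene2	scl2	dup_type
At3g49560	cp	At5g24650	mt; cp	alpha-WGD
At2g23800	ER	At4g36810	cp	alpha-WGD
At1g14450	ER	At2g02510	mt; per; cp	alpha-WGD
At1g17050	cp	At1g78510	ER	alpha-WGD
At1g02510	pm	At4g01840	Va	alpha-WGD
At3g05790	mt; cp	At5g26860	mt	alpha-WGD
At1g55920	cp	At3g13110	mt	alpha-WGD
At3g01330	cy; nu	At5g14960	nu	alpha-WGD
At1g13270	cp	At3g25740	mt; cp	alpha-WGD
At1g13460	per	At3g26020	nu; cy	alpha-WGD
At3g50990	cw	At5g66390	cy	alpha-WGD
At5g04870	per; lb	At3g10660	ER	alpha-WGD
At2g39800	cyb	At3g55610	cy	alpha-WGD
At3g10550	cyb	At5g04540	cy	alpha-WGD
At1g31630	cy	At1g31640	nu	tandem
At2g33110	ER	At2g33120	pm; en	tandem
At3g08720	nu	At3g08730	cy	tandem
At5g39510	TGN/PVC	At5g39630	ER	tandem
At4g15415	nu; cy	At3g21650	mt; cy	other
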