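# Degenerate primers used for the PL7 alginate-lyase clone library (ALG-*)
# and the 16S rRNA V1-V2 survey (M27F/M338R; 454 adaptor and MID tag tails
# omitted -- only the template-annealing cores are modelled here).
# I = inosine, treated as a universal-pairing residue.
name	sequence	orientation
ALG-f1	TAYISIMGITCIGARYTIMGNG	forward
ALG-f2	TAYISIMGIAGIGARYTIMGNG	forward
ALG-r	RTANNNICCIGCYTTRAARTA	reverse
M27F	AKWGTTTGATCMTGGCTCAG	forward
M338R	CTGCWGCCWYCCGTAGRWGT	reverse
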