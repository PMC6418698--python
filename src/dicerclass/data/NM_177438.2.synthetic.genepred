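# Synthetic transcript model standing in for RefSeq NM_177438.2 (DICER1).
# Structure (27 exons, minus strand, 5769-bp CDS incl. stop, 1922 aa,
# exon boundary at c.4206) is faithful; exon/intron sizes are synthetic.
# Columns: name chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds
NM_177438.2	chr14	-	95552000	95614369	95552300	95614249	27	95552000,95553004,95553717,95557190,95559823,95561913,95563921,95565242,95567470,95571302,95574766,95576257,95578391,95580676,95582288,95585287,95589030,95592322,95595046,95598140,95599551,95600624,95602899,95606085,95607919,95611182,95614234,	95552453,95553267,95553813,95557302,95560154,95562202,95564240,95565328,95567772,95571519,95575058,95576537,95578511,95580968,95582403,95585524,95589173,95592583,95595229,95598458,95599737,95600901,95603018,95606274,95608183,95611492,95614369,
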