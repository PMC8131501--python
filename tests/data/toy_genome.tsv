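chrom	length	cen_start	cen_end
chr1	240000000	100800000	104800000
chr2	232000000	97440000	101440000
chr3	224000000	94080000	98080000
chr4	216000000	90720000	94720000
chr5	208000000	87360000	91360000
chr6	200000000	84000000	88000000
chr7	192000000	80640000	84640000
chr8	184000000	77280000	81280000
chr9	176000000	73920000	77920000
chr10	168000000	70560000	74560000
chr11	160000000	67200000	71200000
chr12	152000000	63840000	67840000
chr13	144000000	60480000	64480000
chr14	136000000	57120000	61120000
chr15	128000000	53760000	57760000
chr16	120000000	50400000	54400000
chr17	112000000	47040000	51040000
chr18	104000000	43680000	47680000
chr19	96000000	40320000	44320000
chr20	88000000	36960000	40960000
chr21	80000000	33600000	37600000
chr22	72000000	30240000	34240000
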