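protein	WT1	WT2	WT3	WT4	Het1	Het2	Het3	Hom1	Hom2	Hom3	Hom4
DNM3A	59983	54693	55417	53353	55972	44968	63557	45591	50962	57686	57269
DNM3L	54162	89012	113298	37867	22799	32159	49414	13804	11659	16555	19434
DNMT1	4919641	5455060	5630842	6884143	5497000	6242194	5053342	3860529	4081037	4724012	4264121
DPPA3	94108	101031	129740	145144	63198	79875	99531	69024	72384	70060	98170
KDM1A	29601	36365	32424	24382	26902	24211	27475	39516	42139	38617	31596
KDM1B	327074	270812	355155	246846	310347	284492	281175	318662	327625	358228	332356
KDM2B	50233	51485	51053	71093	61714	67029	60452	33254	32265	39689	30855
SETD2	23861	15949	26758	13344	20455	25077	24062	26025	19342	29895	23273
TIF1B	124681	152886	120861	96040	97449	91378	123001	91063	97666	86946	83262
UHRF1	11675802	9799259	11583398	11091801	9522651	11463501	10829401	7041297	7370016	7605019	9003465
ZFP57	63346	58772	85293	90530	79330	80485	69768	82731	62843	78216	61047
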