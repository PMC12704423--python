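protein	WT1	WT2	WT3	WT4	Het1	Het2	Het3	Hom1	Hom2	Hom3	Hom4
NALP5	29249613	22990500	21701309	34329594	20580396	17248192	16886991	53745	48954	81185	148701
KHDC3	11967394	12713007	14098895	17847493	11147194	10542905	10571504	2788520	2913010	2819019	3640121
NAL14	16254890	12680208	14625793	16085598	16003190	14473409	14968203	12309301	13283708	13467793	13275492
NAL4A	754523	699619	687737	711488	611843	748684	663539	661840	623275	561566	523258
NAL4B	610404	650773	594686	822934	440422	559545	366959	102046	106833	104870	117434
NAL4C	59274	49927	51552	44729	54071	57460	50931	54313	58425	55263	51772
NAL4E	352690	540195	327480	468682	385182	482290	462373	230875	269931	295463	254706
NAL4F	12823795	11083006	11202093	11663105	10163901	9370426	9485609	4863791	5278447	4791200	4382168
NLR9A	259508	270431	263361	353803	279618	289361	279132	151600	176139	191157	195920
NLR9B	1870511	1754859	1775700	2211160	1795169	1794531	1793579	1311269	1523149	1630670	1640971
NLR9C	24646	26505	27227	31581	25771	27969	30852	20928	19472	23700	23276
OOEP	18745907	19388711	17366810	33067496	14524897	12651607	12976194	1400471	1534961	1522400	3306391
PADI6	7054146	4412748	6474884	7464388	8012424	6238770	7107938	6630764	6899897	8170453	7919411
Q4PLS0	3047962	2794192	2727011	3655259	3081808	3236941	3002770	2132909	2539420	2663170	2545841
TLE6	26003597	19599088	23813490	28516604	21401997	19820604	18771899	3313901	3356508	3616430	3896881
ZBED3	1869001	1513690	1581990	2549981	1212480	1078780	1403240	52474	56548	65468	103955
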