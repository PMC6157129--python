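"""Default model parameters: the published causal architecture.

Five major causal SNPs, each paired with its physically nearest CpG site on
the methylation array; 100 background polygenic SNPs (hg2 = 0.001 each); and
five red-herring CpG sites carrying causal-like noise (SD 0.4) but no effect.
Entries are (marker, chrom, position_bp, hg2, coded_allele_freq) for SNPs and
(cpg, chrom, position_bp, v2_mean, v2_sd, v4_ref_mean, v4_ref_sd, linked_snp)
for causal CpGs.
"""

CORR_BASELINE = -0.41881  # observed corr(slope, baseline log-TG) in the source trial
N_REPLICATES = 200
N_SUBJECTS = 717
SD_CAUSAL = 0.4       # per-subject methylation treatment-response SD, causal + red-herring sites
SD_BACKGROUND = 0.03  # measurement-error-level SD for all other CpG sites
BACKGROUND_HG2 = 0.001

# (marker, chrom, position_bp, hg2) -- the five major-effect causal SNPs;
# allele frequencies are not published for these, synthetic cohorts default to 0.3
MAJOR_SNPS = [
    ("rs9661059", 1, 230556033, 0.125),
    ("rs7360046", 6, 5067728, 0.075),
    ("rs1012116", 8, 89466383, 0.1),
    ("rs10828412", 10, 23476515, 0.025),
    ("rs4399565", 17, 13407619, 0.05),
]

# (cpg, chrom, position_bp, v2_mean, v2_sd, v4_ref_mean, v4_ref_sd, linked_snp)
CAUSAL_CPGS = [
    ("cg00000363", 1, 230560793, 0.488, 0.0589, 0.492, 0.3273, "rs9661059"),
    ("cg10480950", 6, 5067127, 0.578, 0.0571, 0.56, 0.3247, "rs7360046"),
    ("cg18772399", 8, 89478349, 0.575, 0.0743, 0.556, 0.3265, "rs1012116"),
    ("cg00045910", 10, 23466070, 0.474, 0.0896, 0.482, 0.3295, "rs10828412"),
    ("cg01242676", 17, 13413600, 0.456, 0.0837, 0.464, 0.328, "rs4399565"),
]

# (cpg, chrom, position_bp) -- non-causal sites given causal-like noise
RED_HERRING_CPGS = [
    ("cg00703276", 3, 130000000),
    ("cg01971676", 7, 43000000),
    ("cg11736230", 14, 100000000),
    ("cg00001261", 16, 3463964),
    ("cg12598270", 18, 33000000),
]

# (marker, chrom, position_bp, coded_allele_freq) -- 100 background polygenic SNPs
BACKGROUND_SNPS = [
    ("rs12037545", 1, 14875400, 0.51764),
    ("rs11102122", 1, 111000000, 0.534672),
    ("rs2004659", 1, 144000000, 0.629111),
    ("rs3806218", 1, 145000000, 0.655718),
    ("rs2352866", 1, 146000000, 0.980535),
    ("rs4637157", 2, 19443, 0.906326),
    ("rs11903036", 2, 584324, 0.53163),
    ("rs4549126", 2, 714368, 0.614964),
    ("rs6758300", 2, 75483393, 0.568735),
    ("rs4667937", 2, 167000000, 0.739659),
    ("rs6785370", 3, 3933764, 0.874696),
    ("rs7628979", 3, 4321347, 0.529197),
    ("rs711664", 3, 4437544, 0.706204),
    ("rs35489229", 3, 5088187, 0.892336),
    ("rs1524557", 3, 81974721, 0.639903),
    ("rs1466475", 4, 80175727, 0.81691),
    ("rs2615479", 4, 88797334, 0.71837),
    ("rs6849123", 4, 91684534, 0.894769),
    ("rs4267808", 4, 110000000, 0.871655),
    ("rs9992755", 4, 111000000, 0.686131),
    ("rs11951861", 5, 84715767, 0.827251),
    ("rs1428900", 5, 84909967, 0.731144),
    ("rs17207011", 5, 85486010, 0.886861),
    ("rs372106", 5, 123000000, 0.619221),
    ("rs7730187", 5, 168000000, 0.518248),
    ("rs1482570", 6, 72738670, 0.867397),
    ("rs1281958", 6, 153000000, 0.587591),
    ("rs9479769", 6, 155000000, 0.546837),
    ("rs9322560", 6, 156000000, 0.857664),
    ("rs9457675", 6, 160000000, 0.641728),
    ("rs4721428", 7, 2137132, 0.678832),
    ("rs6461984", 7, 3314009, 0.703771),
    ("rs17186478", 7, 5779274, 0.603406),
    ("rs2110333", 7, 8151614, 0.708029),
    ("rs1352090", 7, 46160368, 0.615572),
    ("rs4733163", 8, 33653826, 0.625304),
    ("rs2981182", 8, 40010613, 0.53528),
    ("rs2923408", 8, 42570683, 0.542579),
    ("rs16921991", 8, 58386566, 0.796837),
    ("rs10955119", 8, 98468181, 0.58455),
    ("rs7036143", 9, 90615114, 0.827859),
    ("rs2196921", 9, 91748045, 0.81691),
    ("rs12238738", 9, 95433628, 0.622263),
    ("rs10984103", 9, 99679096, 0.652068),
    ("rs1989773", 9, 117000000, 0.990876),
    ("rs10887185", 10, 85670555, 0.914234),
    ("rs481179", 10, 108000000, 0.576642),
    ("rs17586536", 10, 120000000, 0.639903),
    ("rs10788015", 10, 122000000, 0.569343),
    ("rs4339955", 10, 122000000, 0.78528),
    ("rs11030861", 11, 29853551, 0.937956),
    ("rs7947279", 11, 82018398, 0.893552),
    ("rs10895219", 11, 101000000, 0.965937),
    ("rs9888281", 11, 126000000, 0.799878),
    ("rs10790956", 11, 128000000, 0.565085),
    ("rs7138234", 12, 21569984, 0.994526),
    ("rs12426560", 12, 41977227, 0.814477),
    ("rs11183911", 12, 46055518, 0.818735),
    ("rs11113259", 12, 106000000, 0.999392),
    ("rs10219441", 12, 115000000, 0.692214),
    ("rs4427687", 13, 73781335, 0.757299),
    ("rs9318328", 13, 74726372, 0.541971),
    ("rs9573791", 13, 75607873, 0.902068),
    ("rs2329072", 13, 77858815, 0.594282),
    ("rs2633019", 13, 82465113, 0.530414),
    ("rs12897163", 14, 59385513, 0.751217),
    ("rs2121063", 14, 75798908, 0.893552),
    ("rs1676295", 14, 76103995, 0.789538),
    ("rs1430569", 14, 86878849, 0.53528),
    ("rs6575695", 14, 98363450, 0.973236),
    ("rs1390876", 15, 45433081, 0.595499),
    ("rs13313462", 15, 45534066, 0.620438),
    ("rs7180426", 15, 60558330, 0.859489),
    ("rs17477813", 15, 76147746, 0.692214),
    ("rs2072986", 16, 1631107, 0.847324),
    ("rs1077836", 16, 10248642, 0.66545),
    ("rs8052975", 16, 10856764, 0.711679),
    ("rs6497651", 16, 23040046, 0.975669),
    ("rs27817", 16, 48013792, 0.972021),
    ("rs9897174", 17, 49611224, 0.948905),
    ("rs345168", 17, 55565566, 0.959854),
    ("rs9908999", 17, 56215981, 0.909367),
    ("rs1112364", 17, 57597131, 0.905718),
    ("rs12936559", 17, 57680004, 0.935523),
    ("rs1318841", 18, 17138521, 0.967153),
    ("rs17202807", 18, 19434594, 0.955596),
    ("rs339869", 18, 20461587, 0.55292),
    ("rs11083025", 18, 49698325, 0.930657),
    ("rs4325666", 18, 65460176, 0.933698),
    ("rs8111862", 19, 12420713, 0.51399),
    ("rs2453888", 19, 22423985, 0.849757),
    ("rs16999009", 19, 22701498, 0.877129),
    ("rs7252281", 19, 35965262, 0.65204),
    ("rs7254832", 19, 43637691, 0.871046),
    ("rs1974821", 19, 56609547, 0.852798),
    ("rs6056690", 20, 9475353, 0.850365),
    ("rs1415774", 20, 33229277, 0.566302),
    ("rs6093657", 20, 40549705, 0.877737),
    ("rs7260668", 20, 42919440, 0.694039),
    ("rs13042657", 20, 44356316, 0.784063),
]
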