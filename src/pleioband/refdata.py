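"""Bundled reference data for the UAEDIAB five-phenotype cross-phenotype analysis.

Three small tables are embedded so that the full pipeline is runnable and
testable without any download:

* :data:`REGION_CELLS` — the exclusive Venn cells of cytobands shared between
  the diabetes group and the other four UAEDIAB phenotypes, keyed by the
  phenotype combination. Two bands (11p15.4 and 11p15.5) appear in more than
  one printed cell of the source table; they are kept verbatim here, and the
  consequences for re-partitioning are documented in ``docs/methods.md``.
* :data:`SHARED_REGION_SNPS` — the 46 catalog SNP associations falling in the
  eight cytobands shared by at least four phenotypes, with mapped genes,
  band, position and reported genes as raw catalog-style cell strings.
* :data:`PATIENT_GENE_SNV_COUNTS` — per-gene SNV counts from targeted
  sequencing of two diabetic patients, used by the median-threshold
  candidate-gene rule.
"""

from __future__ import annotations

# Canonical phenotype group names used throughout the package.
DIABETES = "T1D/T2D"
OBESITY = "BMI/obesity"
DYSLIPIDEMIA = "dyslipidemia"
SLEEP_APNEA = "sleep apnea"
HYPERTENSION = "hypertension"

PHENOTYPE_GROUPS = (DIABETES, OBESITY, DYSLIPIDEMIA, SLEEP_APNEA, HYPERTENSION)

#: Verbatim trait vocabularies of the five UAEDIAB phenotype groups.
#: Matching is exact (case-insensitive, whitespace-normalized) by default.
TRAIT_VOCABULARY: dict[str, tuple[str, ...]] = {
    DIABETES: ("type 1 diabetes", "type 2 diabetes"),
    OBESITY: ("obesity", "body mass index"),
    DYSLIPIDEMIA: (
        "triglyceride levels",
        "triglycerides",
        "lipid traits",
        "HDL cholesterol-triglycerides",
        "LDL cholesterol levels",
        "HDL cholesterol levels",
        "total cholesterol levels",
    ),
    SLEEP_APNEA: (
        "snoring",
        "obstructive sleep apnea",
        "apnea-hypopnea index",
        "average oxygen saturation during sleep",
        "average respiratory event duration",
    ),
    HYPERTENSION: (
        "hypertension",
        "systolic blood pressure",
        "diastolic blood pressure",
    ),
}

_CELLS_RAW: tuple[tuple[tuple[str, ...], str], ...] = (
    ((OBESITY, DYSLIPIDEMIA, HYPERTENSION, DIABETES), "8p22,1q32.3,12q24.13,7p15.2"),
    ((OBESITY, DYSLIPIDEMIA, SLEEP_APNEA, DIABETES), "11p11.2,6q21,17q12"),
    ((OBESITY, HYPERTENSION, SLEEP_APNEA, DIABETES), "15q26.1"),
    (
        (OBESITY, DYSLIPIDEMIA, DIABETES),
        "16q12.2,19q13.32,16p11.2,5q13.3,11p15.4,10p13,16q23.2,18q21.32,18q11.2,"
        "6p22.3,2p23.3,19q13.11,10p15.1,22q12.3,15q15.1,1p31.3,19p13.2,2q36.3,"
        "11p15.1,12q24.12,12q24.11,11q13.1,2q24.3,1p32.3,1q21.3,10q25.2,6p21.32,"
        "6p21.1,6q23.3,17p13.2,10q21.3,12q24.31,3p25.2,3q21.1",
    ),
    ((DYSLIPIDEMIA, HYPERTENSION, DIABETES), "10q23.33,1q41,1q43,6p21.33,8q24.12"),
    ((OBESITY, HYPERTENSION, DIABETES), "16p12.3,1p13.2"),
    ((OBESITY, SLEEP_APNEA, DIABETES), "1q32.1,1q42.2,11q13.4"),
    (
        (DYSLIPIDEMIA, DIABETES),
        "6q13,6q27,20q13.12,1q42.13,5q11.2,4p16.3,6q24.1,12p13.31,9q34.2,8q24.3,"
        "17p13.1,9p24.2,22q12.2,1p34.3,7q32.2,1p22.1,2q33.2",
    ),
    (
        (OBESITY, DIABETES),
        "6q23.1,10q22.3,8q21.13,2p25.3,4p12,12q13.12,14q31.1,3q27.2,2p16.1,9p21.1,"
        "4q28.2,17q21.32,18q12.3,1p21.3,9q22.31,15q14,9q22.2,5q33.2,14q11.2,3p14.1,"
        "12q12,8q22.3,21q22.3,2p23.2,17p11.2,2q21.3,9q31.3,10q26.13,17p13.3,"
        "11p15.5,11q13.3,8q24.21,7q36.3,1p12,3q23,6p21.2,7p12.1,9p24.1,14q24.1,"
        "18p11.21,13q31.1,5q21.1,2p21,12p12.1,7p14.3,8q22.1,9p21.3",
    ),
    ((HYPERTENSION, DIABETES), "5q31.1,18p11.31,7q22.1,21q22.11,8p11.21,9q21.32"),
    ((SLEEP_APNEA, DIABETES), "2p24.3"),
    (
        (DIABETES,),
        "8q24.11,11q14.3,4q35.1,6q12,17q21.33,3q26.2,17q11.2,4q22.2,22q13.33,"
        "7p21.2,5q22.2,3q13.31,11p12,15q22.2,2q23.3,11q24.3,3q26.33,1q32.2,"
        "10q26.3,19q13.2,4q32.3,14q32.2,2q24.2,7q32.1,9q34.3,3p24.3,Xq28,2q33.1,"
        "3q27.3,13q21.31,6q25.1,13q14.13,13q21.33,13q22.1,16p13.12,20q11.21,"
        "1q21.2,5q14.2,20p12.2,2q14.3,14q23.1,15q24.3,12q13.2,1p22.3,6q15,"
        "16p13.13,18q22.2,2q11.2,5p13.2,15q25.1,4q27,4p15.2,6q22.32,10q23.31,"
        "17q21.1,17q21.2,20p13,13q22.2,7p15.1,10q24.2,10q26.11,13q12.12,8q24.22,"
        "11p15.4,11p15.5,3p23,12q21.2,1p22.2,12q21.1,2q12.1,10q22.1,3q12.3,9p23,"
        "9q21.31,12q14.3,4p16.1,4q31.3,6p24.3,13q12.13,12p11.22,2p23.1,7p14.1,"
        "8q13.2,12p11.21,2p16.2,10q26.12,16q24.1,3p14.3,20q13.31",
    ),
)

#: Exclusive Venn cells: phenotype-combination -> tuple of cytoband labels,
#: verbatim from the published table (including its duplicated bands).
REGION_CELLS: dict[frozenset[str], tuple[str, ...]] = {
    frozenset(groups): tuple(r for r in bands.split(",")) for groups, bands in _CELLS_RAW
}

#: The eight cytobands shared by >= 4 phenotypes (always including diabetes).
SHARED_REGIONS: tuple[str, ...] = (
    "8p22", "1q32.3", "12q24.13", "7p15.2", "11p11.2", "6q21", "17q12", "15q26.1",
)

#: The 46 SNP associations in the shared regions:
#: (rsID, mapped-gene cell, cytoband, chrom:pos, reported-gene cell).
SHARED_REGION_SNPS: tuple[tuple[str, str, str, str, str], ...] = (
    ("rs3817334", "MTCH2", "11p11.2", "11:47629441", "MTCH2"),
    ("rs7124681", "CELF1", "11p11.2", "11:47508395", "CUGBP1"),
    ("rs11066280", "HECTD4", "12q24.13", "12:112379979", "HECTD4"),
    ("rs4430796", "HNF1B", "17q12", "17:37738049", "HNF1B"),
    ("rs2176598", "HSD17B12", "11p11.2", "11:43842728", "HSD17B12"),
    ("rs17696736", "NAA25", "12q24.13", "12:112049014", "Not Reported"),
    ("rs2028299", "AP3S2", "15q26.1", "15:89831025", "AP3S2"),
    ("rs9400239", "FOXO3", "6q21", "6:108656460", "FOXO3"),
    ("rs17126232", "AC124242.3", "8p22", "8:18120141", "ASAH1"),
    ("rs6990042", "SGCZ", "8p22", "8:14316465", "SGCZ"),
    ("rs10742752", "AC103855.3", "11p11.2", "11:45416824", "SYT13"),
    ("rs17630235", "TRAFD1, HECTD4", "12q24.13", "12:112153882", "Not reported"),
    ("rs1439620", "AC013394.1, LINC01578", "15q26.1", "15:92886416", "LOC100507217"),
    ("rs12150665", "GGNBP2", "17q12", "17:36558947", "GGNBP2"),
    ("rs3800229", "FOXO3", "6q21", "6:108675760", "FOXO3"),
    ("rs35424364", "CCDC162P", "6q21", "6:109322403", "C6ORF183, CCDC162P"),
    ("rs1495741", "PSD3, NAT2", "8p22", "8:18415371", "NAT2"),
    ("rs10838738", "MTCH2", "11p11.2", "11:47641497", "MTCH2"),
    ("rs326214", "MADD", "11p11.2", "11:47276809", "LRP4"),
    ("rs74472562", "TSPAN18", "11p11.2", "11:44741205", "RP11-45A12.2, TSPAN18"),
    ("rs1061810", "HSD17B12, AC087521.2, AC087521.4", "11p11.2", "11:43856384", "HSD17B12"),
    ("rs936674", "AC091078.1", "15q26.1", "15:93360368", "RP11-266O8.1"),
    ("rs148024591", "AC091078.1", "15q26.1", "15:93371222", "RP11-266O8.1"),
    ("rs2521501", "FES", "15q26.1", "15:90894158", "FURIN, FES"),
    ("rs8042680", "PRC1, PRC1-AS1", "15q26.1", "15:90978107", "PRC1"),
    ("rs12899811", "VPS33B", "15q26.1", "15:91000846", "PRC1"),
    ("rs79548680", "RCCD1", "15q26.1", "15:90962549", "PRC1"),
    ("rs1877031", "STARD3", "17q12", "17:39657827", "STARD3"),
    ("rs4796285", "AC243830.1, LHX1-DT", "17q12", "17:36824731", "Not reported"),
    ("rs10908278", "HNF1B", "17q12", "17:37739961", "HNF1B, TCF2"),
    ("rs1704198", "AC096639.1", "1q32.3", "1:213737151", "PROX1"),
    ("rs340839", "PROX1", "1q32.3", "1:213988477", "PROX1"),
    ("rs7526425", "AC105275.1, SLC30A1, RD3", "1q32.3", "1:211527316", "SLC30A1"),
    ("rs2075423", "PROX1-AS1", "1q32.3", "1:213981376", "PROX1"),
    ("rs884366", "CCDC162P", "6q21", "6:109252892", "LOC100996634"),
    ("rs149358103", "RPS27AP11, LINC02541", "6q21", "6:11358684", "SOCS5P5, MARCKS"),
    ("rs10261878", "AC010719.1, AC018706.1", "7p15.2", "7:25910925", "NFE2L3, MIR148A"),
    ("rs4719841", "NFE2L3, MIR148A", "7p15.2", "7:25957916", "MIR148A"),
    ("rs4722551", "NFE2L3, MIR148A", "7p15.2", "7:25952206", "MIR148A"),
    ("rs6969780", "HOXA3, HOXA-AS2", "7p15.2", "7:27119517", "HOXA3"),
    ("rs10279895", "HNRNPA1P73, RPL35P4", "7p15.2", "7:27288591", "EVX1, HOXA"),
    ("rs7804356", "SKAP2", "7p15.2", "7:26852046", "Not reported"),
    ("rs4921914", "PSD3, NAT2", "8p22", "8:18414928", "NAT2"),
    ("rs1961456", "NAT2", "8p22", "8:18398199", "NAT2"),
    ("rs115706913", "SGCZ", "8p22", "8:14224308", "Not Reported"),
    ("rs2946504", "TRMT9B", "8p22", "8:12954071", "KIAA1456"),
)

#: Per-gene SNV counts from targeted sequencing of two diabetic patients.
PATIENT_GENE_SNV_COUNTS: dict[str, dict[str, int]] = {
    "Patient 1": {
        "ASAH1": 20, "LRP4": 8, "FES": 9, "HSD17B12": 7, "HNF1B": 4,
        "HECTD4": 2, "SH2B3": 4, "NAT2": 4, "SGCZ": 3, "FURIN": 3,
        "GGNBP2": 5, "TSPAN18": 2, "ALDH2": 1, "STARD3": 1, "MTCH2": 1,
        "NDUFS3": 1, "PRC1": 0, "PTPN11": 1, "CELF1": 3, "NAA25": 2,
    },
    "Patient 2": {
        "ASAH1": 16, "LRP4": 7, "FES": 6, "HSD17B12": 4, "HNF1B": 4,
        "HECTD4": 6, "SH2B3": 4, "NAT2": 2, "SGCZ": 1, "FURIN": 1,
        "GGNBP2": 1, "TSPAN18": 2, "ALDH2": 1, "STARD3": 1, "MTCH2": 2,
        "NDUFS3": 1, "PRC1": 0, "PTPN11": 0, "CELF1": 0, "NAA25": 0,
    },
}

#: Gene-symbol aliases merged when collecting reported genes.
DEFAULT_GENE_ALIASES: dict[str, str] = {"TCF2": "HNF1B"}


def region_memberships() -> dict[str, frozenset[str]]:
    """Per-region phenotype membership implied by the cells.

    A band printed in more than one cell receives the union of the implied
    memberships (the exclusive-partition semantics; see docs/methods.md).
    """
    out: dict[str, set[str]] = {}
    for groups, bands in REGION_CELLS.items():
        for band in bands:
            out.setdefault(band, set()).update(groups)
    return {band: frozenset(groups) for band, groups in out.items()}
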