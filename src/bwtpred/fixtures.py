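"""Packaged study-table fixtures.

Two small tables transcribed by hand from the typeset journal tables at
build time: the 23 paired tumor sets with coding somatic variant lists, and
the 15 whole-genome pairs with noncoding variant counts.  Somatic variants
are stored as ``(gene, protein_change)`` tuples; ``protein_change`` is None
where the table lists only the gene symbol.  ``shared`` holds the shared
coding variant(s) printed for the pair (the 11p15.5 status annotation in the
same printed column is kept separately in ``icr_status``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import FixtureIntegrityError


def _v(*labels: str) -> tuple:
    """Parse 'GENE' or 'GENE p.X' labels into (gene, protein_change) tuples."""
    out = []
    for label in labels:
        parts = label.split(" ", 1)
        out.append((parts[0], parts[1] if len(parts) > 1 else None))
    return tuple(out)


@dataclass(frozen=True)
class PairedCodingRecord:
    patient_id: str
    germline: tuple = ()
    right: tuple = ()
    left: tuple = ()
    shared: tuple = ()
    icr_status: str = ""
    adjacent_kidney: str | None = None
    blood_gt2sd: bool = False


@dataclass(frozen=True)
class PairedNoncodingRecord:
    patient_id: str
    n_noncoding_t1: int = 0
    n_noncoding_t2: int = 0
    n_shared_noncoding: int = 0
    icr_status: str = ""
    germline_genes: tuple = ()

    @property
    def germline_positive(self) -> bool:
        return len(self.germline_genes) > 0


_TABLE1 = (
    PairedCodingRecord(
        "SJWLM066770",
        germline=("REST p.H379P",),
        right=_v("DHX36", "EIF1AX", "HCG22", "RPS10P7"),
        left=_v("ALPK2", "BCORL1", "GUSBP4", "H3F3A", "IZKF4", "PLCH2", "PPFIA4",
                "RBBP4", "STAT4", "REST", "IL2RB", "GRLF1", "LRRC16B"),
        icr_status="LOH", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM066771",
        right=_v("VCX3A"),
        left=_v("LOC26102", "PPCDC", "R3HDM1"),
        icr_status="LOI", blood_gt2sd=True),
    PairedCodingRecord(
        "SJWLM066773",
        germline=("TRIM28 p.Q318*", "BRCA1 p.Q687P"),
        right=_v("CDK13", "TAS2R60"),
        left=_v("ITM2C", "LOC100133161", "LOC339822"),
        icr_status="ROI", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM066776",
        germline=("WT1 p.Q253*",),
        right=_v("AIM1L", "CAMK2B", "CTNNB1 p.S45F", "DHX30", "EBF4", "NLRC5",
                 "OR4C11", "PPL"),
        left=_v("CTNNB1 p.S45del", "DBH", "DDX60", "NANOS1", "NELL1", "TUBB1",
                "ZFHX4", "ATE1", "RERE"),
        icr_status="LOH", adjacent_kidney="ROI R+L", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM066777",
        germline=("TRIM28 p.R795C",),
        right=_v("NCRNA00245", "TCHH"),
        left=_v("C14orf73", "REG3A", "SLC12A1"),
        icr_status="ROI", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM066778",
        right=_v("GPR97", "IL31RA", "RAD17"),
        left=_v("CYC1", "EMX2OS", "KIAA0664", "KIF6", "MAML3", "NES", "NR0B1",
                "PKHD1L1", "SRRM5", "TBX4", "TRMT61B", "ZNF833P"),
        icr_status="LOI", adjacent_kidney="ROI L", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM066779",
        germline=("BLM p.K323R",),
        right=_v("ATP6AP2", "C22orf34", "DACH1", "DROSHA", "MAP7D3", "PITPNM2",
                 "SIX1"),
        left=_v("ABCC12", "DGCR8", "LOC401177", "MARCH7", "SLC17A7", "SIDT2"),
        icr_status="LOI", adjacent_kidney="LOI L", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM066780",
        germline=("WT1 p.E401fs",),
        right=_v("ARHGAP9", "C1orf106", "CHST3", "CTNNB1 p.S45F", "OSBPL8",
                 "PSME3", "RYR1"),
        left=_v("C5orf46", "CTNNB1 p.S45F", "LOC283392", "OR52K2", "SHROOM2"),
        shared=_v("CTNNB1 p.S45F"),
        icr_status="LOH", adjacent_kidney="ROI L", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM066784",
        right=_v("NRP1", "ZNF469"),
        left=_v("AZU1", "C10orf71", "DGCR8", "DSCAML1", "RNASEK"),
        icr_status="LOI", adjacent_kidney="ROI R+L", blood_gt2sd=True),
    PairedCodingRecord(
        "SJWLM066789",
        germline=("DICER1 M1402_E23 splice region",),
        right=_v("CTNNB1", "FAM120C", "GPR27", "LOC730755", "PP1R13L", "RPAP1",
                 "SRRSF4", "TYRO3", "ZNF775"),
        left=_v("ACTR10", "BICD2", "C10orf108", "C1orf86", "C21orf122", "DSC2",
                "IDH3G", "KCND3", "KIAA0125", "NBEAL2"),
        icr_status="LOH", adjacent_kidney="LOH L", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM066792",
        germline=("NYNRIN p.R1592*", "ASXL1 p.V1297I"),
        right=_v("DNHD1", "MAP3K4", "QSOX2", "SPERT", "TROAP"),
        left=(),
        icr_status="LOI", adjacent_kidney="LOI L", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM069391",
        right=_v("CRAT", "ROS1 p.Q1889fs"),
        left=_v("NPRL3", "ROS1 p.Q1889fs"),
        shared=_v("ROS1 p.Q1889fs"),
        icr_status="LOI", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM069394",
        right=_v("SMC1A"),
        left=_v("EIF1AX", "GSPT2", "MAP3K4", "TRIO", "UNC80", "VILL"),
        icr_status="LOI-R/ROI-L", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM069396",
        germline=("WT1 p.R441*",),
        right=(),
        left=_v("APOB", "NBEAL2", "PACS2", "KCNQ1"),
        icr_status="LOH", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM069399",
        right=_v("SPTBN5"),
        left=_v("CHST6", "CLIP1", "DGCR8", "MAGI3", "RERE", "SMC1B"),
        icr_status="LOI", adjacent_kidney="LOI L", blood_gt2sd=True),
    PairedCodingRecord(
        "SJWLM044978",
        right=_v("MCPH1", "STK10"),
        left=_v("ATP6V1B2", "C9orf131", "DOCK9", "LCN10", "MDN1", "PRRC2B",
                "SLC6A20", "TP53", "ZNF805"),
        icr_status="LOI", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM051020",
        right=_v("HIST1H3I", "ZNF664"),
        left=_v("HEATR3"),
        icr_status="LOI", blood_gt2sd=True),
    PairedCodingRecord(
        "SJWLM051024",
        germline=("WT1 p.T305fs",),
        right=_v("NLGN3", "UBE4A", "ZFHX2", "CTNNB1"),
        left=_v("FAM199X", "DSPP", "PPP1R11"),
        icr_status="LOH", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM051026",
        right=_v("ACTB", "AMAC1", "AP2B1", "LDHAL6B", "LZTR1", "NKX2-1",
                 "PRRC2B", "SEC14L3", "TP53", "TTC17"),
        left=_v("CHD4", "EVC", "RBMX", "CASQ2"),
        icr_status="LOI", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM051028",
        germline=("WT1 p.Y337*",),
        right=_v("GLDN", "GPR149", "CTNNB1 p.S45P"),
        left=_v("CCDC61", "CTNNB1 p.S45del", "FAM159B", "SNTG1", "ZNF324",
                "AEBP1"),
        icr_status="LOH", blood_gt2sd=True),
    PairedCodingRecord(
        "SJWLM018908",
        right=_v("CRIPAK", "TMEM151B"),
        left=(),
        icr_status="LOI", blood_gt2sd=True),
    PairedCodingRecord(
        "SJWLM043953",
        germline=("CDC73 p.M1T",),
        right=_v("ANKRD34B", "DNAH5", "FRG1"),
        left=(),
        icr_status="ROI", blood_gt2sd=False),
    PairedCodingRecord(
        "SJWLM051025",
        right=_v("RYR1", "IRS4"),
        left=(),
        icr_status="LOI", blood_gt2sd=True),
)

_TABLE2 = (
    PairedNoncodingRecord("SJWLM066770", 136, 119, 0, "LOH", ("REST",)),
    PairedNoncodingRecord("SJWLM066771", 54, 74, 6, "LOI", ()),
    PairedNoncodingRecord("SJWLM066773", 38, 41, 0, "ROI", ("TRIM28", "BRCA1")),
    PairedNoncodingRecord("SJWLM066776", 122, 174, 5, "LOH", ("WT1",)),
    PairedNoncodingRecord("SJWLM066777", 69, 59, 0, "ROI", ("TRIM28",)),
    PairedNoncodingRecord("SJWLM066778", 379, 68, 1, "LOI", ()),
    PairedNoncodingRecord("SJWLM066779", 83, 230, 0, "LOI", ("BLM",)),
    PairedNoncodingRecord("SJWLM066780", 97, 104, 0, "LOH", ("WT1",)),
    PairedNoncodingRecord("SJWLM066784", 73, 83, 1, "LOI", ()),
    PairedNoncodingRecord("SJWLM066789", 125, 58, 2, "LOH", ("DICER1",)),
    PairedNoncodingRecord("SJWLM066792", 79, 16, 1, "LOI", ("ASXL1", "NYNRIN")),
    PairedNoncodingRecord("SJWLM069391", 102, 121, 63, "LOI", ()),
    PairedNoncodingRecord("SJWLM069394", 43, 104, 1, "LOI/ROI", ()),
    PairedNoncodingRecord("SJWLM069396", 38, 90, 2, "LOH", ("WT1",)),
    PairedNoncodingRecord("SJWLM069399", 136, 55, 1, "LOI", ()),
)

EXPECTED_TABLE1_ROWS = 23
EXPECTED_TABLE2_ROWS = 15


def load_table1_fixture() -> pd.DataFrame:
    """The 23 paired tumor sets with coding somatic variant lists."""
    if len(_TABLE1) != EXPECTED_TABLE1_ROWS:
        raise FixtureIntegrityError(
            f"paired-coding fixture has {len(_TABLE1)} rows, "
            f"expected {EXPECTED_TABLE1_ROWS}"
        )
    ids = [r.patient_id for r in _TABLE1]
    if len(set(ids)) != len(ids):
        raise FixtureIntegrityError("duplicate patient ids in paired-coding fixture")
    return pd.DataFrame(
        [{
            "patient_id": r.patient_id,
            "germline": r.germline,
            "right": r.right,
            "left": r.left,
            "shared": r.shared,
            "icr_status": r.icr_status,
            "adjacent_kidney": r.adjacent_kidney,
            "blood_gt2sd": r.blood_gt2sd,
        } for r in _TABLE1]
    )


def load_table2_fixture() -> pd.DataFrame:
    """The 15 whole-genome pairs with noncoding somatic variant counts."""
    if len(_TABLE2) != EXPECTED_TABLE2_ROWS:
        raise FixtureIntegrityError(
            f"paired-noncoding fixture has {len(_TABLE2)} rows, "
            f"expected {EXPECTED_TABLE2_ROWS}"
        )
    ids = [r.patient_id for r in _TABLE2]
    if len(set(ids)) != len(ids):
        raise FixtureIntegrityError("duplicate patient ids in paired-noncoding fixture")
    return pd.DataFrame(
        [{
            "patient_id": r.patient_id,
            "n_noncoding_t1": r.n_noncoding_t1,
            "n_noncoding_t2": r.n_noncoding_t2,
            "n_shared_noncoding": r.n_shared_noncoding,
            "icr_status": r.icr_status,
            "germline_genes": r.germline_genes,
            "germline_positive": r.germline_positive,
        } for r in _TABLE2]
    )
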