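"""Clinical/histopathology cohort table and subtype comparisons.

The packaged cohort fixture reconstructs the study population row-by-row
from its printed per-subtype marginal counts: 60 dogs with thyroid
carcinoma, 54 follicular (FTC) and 6 medullary (MTC) by calcitonin
expression (IHC and/or transcript), of which 30 were sequenced.  Ordinal
histopathology fields (histologic pattern, differentiation grade, nuclear
atypia, calcitonin and HER2 IHC scores) match the per-subtype category
counts exactly; continuous and survival fields are synthetic values
consistent with the printed medians and ranges, and the joint distribution
across columns is synthetic (only the margins are constrained).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import OrdinalTable, mann_whitney

__all__ = [
    "SEQUENCED_SAMPLES",
    "SEQUENCED_MTC",
    "clinical_cohort",
    "subtype_fraction",
    "compare_ordinal",
    "ordinal_table_from_cohort",
]

# Sequenced tumor ids appearing in the cohort's variant/fusion analyses;
# ids prefixed TCS are synthetic fill for the unnamed remainder of the
# 30-sample sequencing roster.
SEQUENCED_SAMPLES = (
    "TC22", "TC67", "TC538", "TC627", "TC640", "TC902", "TC1020", "TC1088",
    "TC1123", "TC1164", "TC1218", "TC1241", "TC1473", "TC1593", "TC1601",
    "TC1744", "TC1936", "TC1979", "TC2011", "TC2089", "TC2110", "TC2288",
    "TC2289", "TC2402", "TCS01", "TCS02", "TCS03", "TCS04", "TCS05", "TCS06",
)

#: The five sequenced medullary tumors (transcriptomic cluster T2).
SEQUENCED_MTC = ("TC1020", "TC1601", "TC1936", "TC2289", "TCS01")

_ORDINAL_LEVELS = {
    "histologic_pattern": ("follicular", "follicular-compact", "compact"),
    "differentiation": ("well", "moderate", "poor"),
    "nuclear_atypia": ("mild", "moderate", "marked"),
    "calcitonin_ihc": ("negative", "positive"),
    "her2_asco": ("0", "1", "2", "3"),
    "her2_pena": ("0", "1", "2", "3"),
}

# per-subtype category counts, in the level order above
_MARGINS = {
    "histologic_pattern": {"FTC": (24, 24, 6), "MTC": (0, 2, 4)},
    "differentiation": {"FTC": (20, 30, 4), "MTC": (0, 2, 4)},
    "nuclear_atypia": {"FTC": (33, 17, 4), "MTC": (1, 4, 1)},
    "calcitonin_ihc": {"FTC": (54, 0), "MTC": (1, 5)},
    "her2_asco": {"FTC": (8, 20, 15, 11), "MTC": (5, 1, 0, 0)},
    "her2_pena": {"FTC": (8, 20, 19, 7), "MTC": (5, 1, 0, 0)},
}


def _expand(counts, levels):
    out = []
    for c, lvl in zip(counts, levels):
        out.extend([lvl] * c)
    return out


def _diameters_ftc():
    # 54 values: min 2.5, max 17.0, median 4.25 (average of ranks 27/28)
    low = np.round(np.linspace(2.5, 4.2, 26), 2)
    high = np.round(np.linspace(4.3, 17.0, 26), 2)
    return np.concatenate([low, [4.25, 4.25], high])


def clinical_cohort(seed: int = 2024) -> pd.DataFrame:
    """The 60-dog cohort table.

    Columns: sample_id, subtype (FTC/MTC by calcitonin expression),
    sequenced (bool), the six ordinal histopathology fields,
    tumor_diameter_cm, metastasis_at_diagnosis, and synthetic survival
    fields (pfi_days/pfi_event, st_days/st_event).
    """
    rng = np.random.default_rng(seed)
    mtc_seq = list(SEQUENCED_MTC)
    ftc_seq = [s for s in SEQUENCED_SAMPLES if s not in set(mtc_seq)]
    ftc_ids = ftc_seq + [f"TCN{i:02d}" for i in range(1, 30)]  # 25 + 29 = 54
    mtc_ids = mtc_seq + ["TCN30"]  # 5 + 1 = 6

    rows = []
    for subtype, ids in (("FTC", ftc_ids), ("MTC", mtc_ids)):
        cols = {
            f: _expand(_MARGINS[f][subtype], _ORDINAL_LEVELS[f]) for f in _MARGINS
        }
        if subtype == "FTC":
            diam = _diameters_ftc()
            meta = _expand((43, 10, 1), ("absent", "present", "unknown"))
        else:
            diam = np.array([3.0, 3.5, 4.9, 5.0, 7.0, 8.5])
            meta = _expand((3, 3, 0), ("absent", "present", "unknown"))
        # synthetic survival: long-survivor cohort with heavy censoring
        n = len(ids)
        pfi = np.round(rng.exponential(1600, n)).clip(30, 1892)
        st = np.maximum(pfi, np.round(rng.exponential(1900, n)).clip(38, 3138))
        pfi_event = rng.random(n) < 0.4
        st_event = rng.random(n) < 0.35
        for i, sid in enumerate(ids):
            rows.append(
                {
                    "sample_id": sid,
                    "subtype": subtype,
                    "sequenced": sid in set(SEQUENCED_SAMPLES),
                    **{f: cols[f][i] for f in _MARGINS},
                    "tumor_diameter_cm": float(diam[i]),
                    "metastasis_at_diagnosis": meta[i],
                    "pfi_days": float(pfi[i]),
                    "pfi_event": bool(pfi_event[i]),
                    "st_days": float(st[i]),
                    "st_event": bool(st_event[i]),
                }
            )
    return pd.DataFrame(rows)


def subtype_fraction(cohort: pd.DataFrame, subtype: str = "FTC") -> float:
    """Fraction of dogs with the given calcitonin-based subtype."""
    return float((cohort["subtype"] == subtype).mean())


def ordinal_table_from_cohort(cohort: pd.DataFrame, field: str) -> OrdinalTable:
    """Two-group ordinal table (FTC vs MTC) for a histopathology field;
    'unknown'/'unavailable' values are dropped."""
    levels = _ORDINAL_LEVELS[field]
    counts = {}
    for subtype in ("FTC", "MTC"):
        sub = cohort[cohort["subtype"] == subtype][field]
        counts[subtype] = [int((sub == lvl).sum()) for lvl in levels]
    return OrdinalTable(categories=levels, counts=counts)


def compare_ordinal(cohort: pd.DataFrame, field: str, mode: str = "exact"):
    """Exact Mann-Whitney comparison of an ordinal histopathology field
    between FTC and MTC.  Returns (U, two-sided p)."""
    return mann_whitney(ordinal_table_from_cohort(cohort, field), mode=mode)
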