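"""Published contingency counts of the reference study, as fixtures.

These are the raw printed counts of the external-validation study the
pipeline emulates: grid- and slide-level confusion counts of the AI
(overall and per sampling procedure, with the grid table split into
cancer/HGD and benign slide rows), and the four per-reader revision
direction counts of the AI-exposed reader study. Feeding them through the
metrics module reproduces every printed estimate; they also calibrate the
synthetic-data defaults.
"""

from __future__ import annotations

from .errors import FixtureLookupError
from .metrics import ConfusionCounts
from .reader_study import RevisionTable

# cohort marginals
TOTAL_GRIDS = 3_589_476
POSITIVE_GRIDS = 75_914
NEGATIVE_GRIDS = 3_513_562
TOTAL_SLIDES = 1_418
POSITIVE_SLIDES = 164
NEGATIVE_SLIDES = 1_254
SURGICAL_SLIDES = 238
ENDOSCOPIC_SLIDES = 1_180
LESION_AREA_MM2_RANGE = (0.5, 349.25)

# grid-level AI confusion counts; the printed table splits truth-negative
# grids across cancer/HGD and benign slide rows — pooled here, with the
# raw per-row split kept alongside.
TABLE2A_ROWS = {
    "overall": {"cancer_or_hgd": dict(n=297_403, tp=68_510, fn=7_404,
                                      tn=211_823, fp=9_666),
                "benign": dict(n=3_292_073, tn=3_182_282, fp=109_791)},
    "endoscopic": {"cancer_or_hgd": dict(n=103_355, tp=19_961, fn=2_201,
                                         tn=75_028, fp=6_165),
                   "benign": dict(n=3_188_512, tn=3_079_799, fp=108_713)},
    "surgical": {"cancer_or_hgd": dict(n=194_048, tp=48_549, fn=5_203,
                                       tn=136_795, fp=3_501),
                 "benign": dict(n=103_561, tn=102_483, fp=1_078)},
}


def _pool(stratum: str) -> ConfusionCounts:
    rows = TABLE2A_ROWS[stratum]
    c, b = rows["cancer_or_hgd"], rows["benign"]
    return ConfusionCounts(tp=c["tp"], fn=c["fn"],
                           tn=c["tn"] + b["tn"], fp=c["fp"] + b["fp"],
                           granularity="grid", stratum=stratum)


TABLE2A = {name: _pool(name) for name in TABLE2A_ROWS}

# slide-level AI confusion counts
TABLE2B = {
    "overall": ConfusionCounts(tp=163, fn=1, tn=856, fp=398,
                               granularity="slide", stratum="overall"),
    "endoscopic": ConfusionCounts(tp=36, fn=0, tn=776, fp=368,
                                  granularity="slide", stratum="endoscopic"),
    "surgical": ConfusionCounts(tp=127, fn=1, tn=80, fp=30,
                                granularity="slide", stratum="surgical"),
}

# per-reader revision-direction counts (revised grids overlap between
# readers, so the column sums exceed the printed distinct-grid totals)
TABLE3 = {
    "JP1": dict(fn_to_tp=122, tp_to_fn=2, fp_to_tn=15, tn_to_fp=51),
    "JP2": dict(fn_to_tp=540, tp_to_fn=5, fp_to_tn=536, tn_to_fp=117),
    "JP3": dict(fn_to_tp=1_321, tp_to_fn=143, fp_to_tn=823, tn_to_fp=397),
    "SP": dict(fn_to_tp=1_403, tp_to_fn=10, fp_to_tn=594, tn_to_fp=58),
}
TABLE3_DISTINCT_TOTALS = dict(fn_to_tp=3_169, tp_to_fn=158,
                              fp_to_tn=1_596, tn_to_fp=574,
                              revised_positive=3_327, revised_negative=2_170)

# published averaged reader operating points (grid level)
READER_BASELINE_SENSITIVITY = 0.8180
READER_BASELINE_SPECIFICITY = 0.9993

# AI grid-level operating point implied by TABLE2A["overall"]
AI_GRID_SENSITIVITY = TABLE2A["overall"].tp / TABLE2A["overall"].n_positive
AI_GRID_SPECIFICITY = TABLE2A["overall"].tn / TABLE2A["overall"].n_negative


def load_fixture(name: str):
    """Look up a printed-table fixture by name.

    Names: ``table2a_<stratum>`` / ``table2b_<stratum>`` (stratum overall,
    endoscopic, surgical) -> ConfusionCounts; ``table3_<reader>`` (jp1,
    jp2, jp3, sp) -> RevisionTable with McNemar p-values;
    ``table3_<reader>_positive`` / ``_negative`` -> the (beneficial,
    harmful) discordant-count pair.
    """
    key = name.lower()
    try:
        if key.startswith("table2a_"):
            return TABLE2A[key[len("table2a_"):]]
        if key.startswith("table2b_"):
            return TABLE2B[key[len("table2b_"):]]
        if key.startswith("table3_"):
            rest = key[len("table3_"):]
            if rest.endswith("_positive"):
                d = TABLE3[rest[:-len("_positive")].upper()]
                return (d["fn_to_tp"], d["tp_to_fn"])
            if rest.endswith("_negative"):
                d = TABLE3[rest[:-len("_negative")].upper()]
                return (d["fp_to_tn"], d["tn_to_fp"])
            d = TABLE3[rest.upper()]
            return RevisionTable(reader_id=rest.upper(),
                                 **d).with_pvalues()
    except KeyError:
        pass
    raise FixtureLookupError(f"unknown fixture name: {name!r}")
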