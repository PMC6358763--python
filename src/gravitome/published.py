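"""Published reference inputs: printed count tables and continuous-gene lists.

These are the numbers printed in the study's result tables, packaged as inputs
for worked examples and validation: per-comparison up/down tallies of
differentially expressed probe sets, per-category temporal counts, and the
fold-change tables of the probe sets called "continuous" across platforms.
Nothing here is an output of this package; the pipeline recomputes comparable
quantities from data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# -- Temporal category counts ---------------------------------------------

#: Jurkat T cells, hypergravity time course (20 s at 1.8 g vs 75 s at up to
#: 13.5 g) over the 184 panel probe sets of the transcriptome array.
JURKAT_HYPERGRAVITY_CATEGORY_COUNTS = {
    "no_response": 43,
    "continuous": 21,
    "adaptation": 49,
    "late_response": 71,
}

#: Jurkat T cells, microgravity time course (20 s vs 300 s), 184 probe sets.
JURKAT_MICROGRAVITY_CATEGORY_COUNTS = {
    "no_response": 165,
    "continuous": 0,
    "adaptation": 10,
    "late_response": 9,
}

#: U937 cells, hypergravity time course, 375 panel probe sets.  The printed
#: adaptation row gives "38 probe sets (36.8%)"; 38/375 is 10.1% while
#: 138/375 is 36.8% and only 138 completes the partition (174+4+138+59=375),
#: so 138 is stored here.  This table is internally inconsistent in print and
#: is used for illustration only, never as a validation target.
U937_HYPERGRAVITY_CATEGORY_COUNTS = {
    "no_response": 174,
    "continuous": 4,
    "adaptation": 138,
    "late_response": 59,
}

#: U937 cells, microgravity time course, 375 probe sets.
U937_MICROGRAVITY_CATEGORY_COUNTS = {
    "no_response": 319,
    "continuous": 1,
    "adaptation": 20,
    "late_response": 35,
}

# -- Per-comparison counts of differentially expressed probe sets ----------

#: Jurkat, 23rd DLR parabolic flight campaign: (up, down) per comparison.
JURKAT_PFC_COMPARISON_COUNTS = {
    "IF_1g_vs_HW_1g_GC": (85, 29),
    "BL_hyp_g_vs_IF_1g": (19, 19),
    "MU_G_vs_BL_hyp_g": (3, 11),
    "BL_hyp_g_vs_HW_1g_GC": (51, 19),
}

#: Jurkat, TEXUS-51 suborbital rocket flight.
JURKAT_TEXUS51_COMPARISON_COUNTS = {
    "IF_1g_vs_HW_1g_GC": (29, 5),
    "BL_hyp_g_vs_IF_1g": (37, 114),
    "MU_G_vs_BL_hyp_g": (5, 4),
    "MU_G_vs_IF_1g": (33, 109),
    "BL_hyp_g_vs_HW_1g_GC": (41, 82),
    "HW_1g_GC_vs_CC": (125, 52),
}

#: U937, 19th DLR parabolic flight campaign.
U937_PFC_COMPARISON_COUNTS = {
    "IF_1g_vs_HW_1g_GC": (15, 30),
    "BL_hyp_g_vs_IF_1g": (61, 43),
    "MU_G_vs_BL_hyp_g": (6, 15),
    "BL_hyp_g_vs_HW_1g_GC": (75, 67),
}

#: U937, TEXUS-49 suborbital rocket flight.
U937_TEXUS49_COMPARISON_COUNTS = {
    "MU_G_vs_BL_hyp_g": (5, 33),
    "BL_hyp_g_vs_HW_1g_GC": (90, 15),
    "MU_G_vs_HW_1g_GC": (6, 9),
}

# -- Continuous-response fold-change tables --------------------------------


def _load(name: str) -> pd.DataFrame:
    with resources.files("gravitome.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def jurkat_continuous_hypergravity() -> pd.DataFrame:
    """The 21 Jurkat probe sets regulated continuously across 20 s and 75 s of
    hypergravity: signed fold changes on both platforms, all significant."""
    return _load("jurkat_continuous_hypergravity.tsv")


def u937_continuous_hypergravity() -> pd.DataFrame:
    """The 4 U937 probe sets (3 genes) continuous across hypergravity exposures."""
    return _load("u937_continuous_hypergravity.tsv")


def u937_continuous_microgravity() -> pd.DataFrame:
    """The single U937 probe set (IL1B) continuous across microgravity exposures."""
    return _load("u937_continuous_microgravity.tsv")
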