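"""Packaged fixture data.

The bundled table lists the experimentally assayed 20-nt thrombin
aptamer loops: 27 model-designed candidates (r1-r27), the four
previously known binders ThA-ThD, and the six intermediates (p1-p6) on
the ThA-to-r9 mutational path.  Columns carry the published scores of
the count-trained (RBM-SC) and unique-trained (RBM-SU) models, the
threshold-based binding prediction, the gel-shift outcome (B / NB / NA),
the targeted thrombin exosite, and the Hamming distance to the closest
round-8 sequence.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_NA_STRINGS = ["NA"]


def load_table1() -> pd.DataFrame:
    """The packaged designed-sequence assay table as a DataFrame."""
    ref = resources.files("selexrbm") / "data" / "table1.tsv"
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t", na_values=_NA_STRINGS,
                            keep_default_na=False)
    return frame


def table1_designed() -> pd.DataFrame:
    """Only the 27 designed/tested candidates r1-r27."""
    frame = load_table1()
    return frame[frame["label"].str.fullmatch(r"r\d+")].reset_index(drop=True)


def table1_scores_labels(model: str = "ll_rbm_su"):
    """Scores and binary binder labels for the r1-r27 candidates.

    Returns (scores, labels, frame); labels are True for gel-shift
    binders.  All 27 candidates have a definite assay outcome.
    """
    frame = table1_designed()
    labels = (frame["binding"] == "B").to_numpy()
    scores = frame[model].to_numpy(dtype=float)
    return scores, labels, frame
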