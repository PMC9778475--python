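"""Cell-hashing demultiplexing for a two-sample hashed experiment.

Hashtag 1 marks vehicle-control cells (``ctr``), hashtag 2 marks
drug-treated cells (``pnb``).  The rule is deliberately simple: a cell
with counts for only one hashtag belongs to that sample; otherwise the
larger count must exceed the smaller by a ratio threshold (default
10x), and anything ambiguous is a ``multiplet`` — a droplet that may
have captured cells from both flasks.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

CONTROL = "ctr"
TREATED = "pnb"
MULTIPLET = "multiplet"

LABELS = (CONTROL, TREATED, MULTIPLET)

__all__ = ["assign_cell", "demultiplex", "CONTROL", "TREATED", "MULTIPLET", "LABELS"]


def assign_cell(h1: int, h2: int, ratio_threshold: float = 10.0) -> str:
    """Label one cell from its two hashtag counts.

    Zero-vs-nonzero evidence wins outright; otherwise the inclusive
    ratio rule ``a >= ratio_threshold * b`` applies.  (0, 0) carries no
    evidence and is a multiplet.
    """
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must be > 1")
    if h1 < 0 or h2 < 0:
        raise ValueError("hashtag counts must be non-negative")
    if h1 == 0 and h2 == 0:
        return MULTIPLET
    if h1 == 0:
        return TREATED
    if h2 == 0:
        return CONTROL
    if h1 >= ratio_threshold * h2:
        return CONTROL
    if h2 >= ratio_threshold * h1:
        return TREATED
    return MULTIPLET


def demultiplex(
    hashtags: pd.DataFrame, ratio_threshold: float = 10.0
) -> tuple[pd.Series, dict[str, int]]:
    """Label every barcode and tally the three groups.

    ``hashtags`` is a DataFrame indexed by barcode with two columns
    (hashtag 1, hashtag 2).  Returns the per-cell labels and a summary
    ``{label: count}`` covering all three labels.
    """
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must be > 1")
    if hashtags.index.has_duplicates:
        raise ValueError("duplicate barcodes in hashtag table")
    if hashtags.shape[1] != 2:
        raise ValueError("exactly two hashtag columns expected")
    h = hashtags.to_numpy()
    if h.size and h.min() < 0:
        raise ValueError("hashtag counts must be non-negative")
    h1 = h[:, 0].astype(float)
    h2 = h[:, 1].astype(float)

    labels = np.full(len(hashtags), MULTIPLET, dtype=object)
    only1 = (h1 > 0) & (h2 == 0)
    only2 = (h2 > 0) & (h1 == 0)
    ratio1 = (h1 > 0) & (h2 > 0) & (h1 >= ratio_threshold * h2)
    ratio2 = (h1 > 0) & (h2 > 0) & (h2 >= ratio_threshold * h1)
    labels[only1 | ratio1] = CONTROL
    labels[only2 | ratio2] = TREATED

    series = pd.Series(labels, index=hashtags.index, name="label")
    counts = Counter(labels)
    summary = {lab: int(counts.get(lab, 0)) for lab in LABELS}
    return series, summary
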