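"""Bundled example data.

A small published-style summary of a bread-wheat recurrent-selection
evaluation: mean grain yield (g/plot) per entry under rainfed (RF, stress)
and restricted-irrigation (RI, non-stress) treatments for ten half-sib
families, the pooled half-sib population ("hsib"), the unselected base
population, two commercial check varieties, and the two parents of the
original cross.  The ``hsib`` row doubles as the reference for the
normalized drought indices (its own MRP is then exactly 2 and REI exactly
1).
"""

from __future__ import annotations

import io

import pandas as pd

from .trial import TrialDataset

_YIELD_MEANS_CSV = """\
entry,pop_class,y_rf,y_ri
hs116,halfsib,595.7,564.9
hs26,halfsib,621,551.5
hs35,halfsib,593.9,584.3
hs39,halfsib,626,602.3
hs48,halfsib,616.5,648.8
hs65,halfsib,710.8,638.8
hs68,halfsib,623,628.3
hs79,halfsib,652.8,596.7
hs86,halfsib,709.3,566.4
hs91,halfsib,678.1,622
hsib,halfsib,650.9,597
HD2987,check,637.5,525
HD3043,check,695,462.5
HI1500,parent,335.7,726.1
HUW510,parent,182,651.6
base,base,353.6,673.2
"""

#: Entry whose RF/RI means act as reference for MRP, REI, and STI.
EXAMPLE_REFERENCE_ENTRY = "hsib"


def example_yield_means() -> pd.DataFrame:
    """Per-entry mean yields (g/plot) under RF and RI, one row per entry."""
    return pd.read_csv(io.StringIO(_YIELD_MEANS_CSV))


def example_trial_dataset() -> TrialDataset:
    """The same means re-encoded as a 32-plot dataset (one plot per
    entry-treatment cell, single year and replicate)."""
    means = example_yield_means()
    rows = []
    for _, row in means.iterrows():
        for treatment, col in (("RF", "y_rf"), ("RI", "y_ri")):
            rows.append(
                {
                    "entry": row["entry"],
                    "pop_class": row["pop_class"],
                    "treatment": treatment,
                    "year": 1,
                    "rep": 1,
                    "yield": row[col],
                }
            )
    return TrialDataset(pd.DataFrame(rows), ["yield"])
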