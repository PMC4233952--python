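"""Packaged reference tables.

Currently one: the histologic grading of the 17-donor knee-cartilage cohort
(modified Mankin scores with joint status), used to derive disease-group
labels for the chase experiments.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .differential import categorize_sample


def load_cohort_grading(categorize: bool = True) -> pd.DataFrame:
    """Load the donor histology table (sample_ref, age, sex, joint status,
    modified Mankin score).

    With ``categorize=True`` (default) a ``group`` column is added by
    applying the grading rule: non-OA joints scoring <10 are normal, OA
    joints are intact below 10 and fibrillated at 10 or above.
    """
    ref = resources.files("mrnadecay.data").joinpath("cohort_grading.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t")
    if categorize:
        table["group"] = [
            categorize_sample(js, score)
            for js, score in zip(table["joint_status"], table["mankin_score"])
        ]
    return table
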