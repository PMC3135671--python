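"""Packaged reference data.

Two small published tables ship with the package as worked-example
inputs:

* the experimentally measured IC50 values (μm) of the maltol-derived
  inhibitors AM-2, AM-5 and AM-6 against MMP-2 and MMP-3, including the
  left-censored ">50" entry for AM-6 / MMP-2;
* the published filtered ensemble-average docking scores (mean ± SD)
  of the same ligand/receptor pairs, on the empirical scale where
  ~100 units correspond to one order of magnitude of IC50.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .selectivity import InhibitionRecord, read_inhibition_table

__all__ = ["load_ic50_table", "load_reported_ensemble_scores", "data_path"]


def data_path(name: str):
    return files("confsel.data").joinpath(name)


def load_ic50_table() -> list[InhibitionRecord]:
    """Measured IC50 values (μm), censored entries flagged."""
    return read_inhibition_table(data_path("ic50_mmp.tsv"))


def load_reported_ensemble_scores() -> pd.DataFrame:
    """Published filtered ensemble-average scores (ligand, receptor, mean, sd)."""
    return pd.read_csv(data_path("reported_ensemble_scores.tsv"), sep="\t")
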