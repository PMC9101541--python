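"""Bundled reference tables for the 5HT6 screening campaign.

Two small published tables ship with the package as plain CSV:

* ``admet_candidates`` — QikProp-style ADMET descriptors of the ten
  natural-product candidate antagonists, including the printed Lipinski
  (VRF) and Jorgensen (VRT) violation counts used as a regression oracle
  for the rule engine.
* ``reference_ligands`` — docking scores and EIIP/AQVN values of the six
  clinical-stage 5HT6 antagonists plus the ten candidates.

Numeric columns in the sources use the unicode minus sign; the loaders
normalize it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chem_io import PropertyRow, read_property_table

__all__ = [
    "admet_candidates",
    "admet_candidate_rows",
    "reference_ligands",
    "SEROTONIN_FORMULA",
]

#: Molecular formula of serotonin, the 5HT6 receptor's natural ligand.
SEROTONIN_FORMULA = "C10H12N2O"


def _data_path(name: str):
    return resources.files("eiipscreen.data").joinpath(name)


def admet_candidates() -> pd.DataFrame:
    """ADMET descriptor table of the ten candidate compounds."""
    with resources.as_file(_data_path("admet_candidates.csv")) as p:
        df = pd.read_csv(p)
    for col in df.columns[1:]:
        df[col] = pd.to_numeric(df[col].astype(str).str.replace("−", "-", regex=False))
    return df


def admet_candidate_rows() -> list[PropertyRow]:
    """The same table as typed PropertyRow records."""
    with resources.as_file(_data_path("admet_candidates.csv")) as p:
        return read_property_table(p)


def reference_ligands() -> pd.DataFrame:
    """Docking scores and EIIP/AQVN of clinical + candidate ligands."""
    with resources.as_file(_data_path("reference_ligands.csv")) as p:
        df = pd.read_csv(p)
    for col in ("gold_score", "vina_dg_kcal", "aqvn", "eiip"):
        df[col] = pd.to_numeric(df[col].astype(str).str.replace("−", "-", regex=False))
    return df
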