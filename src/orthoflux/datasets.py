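"""Packaged literature datasets.

Small curated tables shipped with the package:

* ``essentiality_literature`` — predicted-essential mouse metabolic genes
  with a published homozygous-knockout phenotype (lethal yes/no) and the
  metabolic subgroup of their reactions;
* ``knockout_subsystem_counts`` — per-subsystem counts of reactions with
  decreased/increased flux capacity for four simulated knockouts
  (PGM1, FUT9, SORD, DHCR7), plus the p-value as originally printed;
* ``lpl_knockout_counts`` — the headline decreased/increased counts for
  the lipoprotein-lipase (LPL) knockout in glycan and lipid metabolism.

These are consumed as inputs to the statistics layer (the shift test is
recomputed from the raw counts, never read from the p-value column).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("orthoflux.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_essentiality_literature() -> pd.DataFrame:
    """Columns: gene, subgroup, lethal (yes/no), comment."""
    return _load("essentiality_literature.tsv")


def lethal_fraction() -> float:
    """Fraction of predicted-essential genes with literature data whose
    knockout is lethal in vivo (model true-positive rate)."""
    df = load_essentiality_literature()
    return float((df["lethal"] == "yes").mean())


def load_knockout_subsystem_counts() -> pd.DataFrame:
    """Columns: knockout, subsystem, n_down, n_up, printed_p."""
    return _load("knockout_subsystem_counts.tsv")


def load_lpl_knockout_counts() -> pd.DataFrame:
    """Columns: subsystem, n_down, n_up."""
    return _load("lpl_knockout_counts.tsv")
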