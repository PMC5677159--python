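"""Published summary tables from the rice fsv1/Gui99 ovule WGBS study.

Three small reference tables ship with the package as TSV: the read/mapping
summary, the per-chromosome x context methylation-level table, and the
significantly differentially methylated miRNA-promoter table (84 rows).
They serve as arithmetic worked examples: the report conventions
(rate percentages, totals rows, significance labels) can be recomputed from
the printed counts and compared against the printed values.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    path = resources.files("ovulemeth") / "data" / name
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def load_mapping_table() -> pd.DataFrame:
    """Read counts and mapping/conversion rates per sample (two rows)."""
    return _load("wgbs_mapping_reference.tsv")


def load_methylation_table() -> pd.DataFrame:
    """Per-chromosome site and methylated-site counts per context, with the
    printed percent columns and totals rows (12 chromosomes x 2 samples)."""
    return _load("methylation_levels_reference.tsv")


def load_mirna_table() -> pd.DataFrame:
    """The 84 significantly differentially methylated miRNA promoters with
    printed log2 fold-changes, direction, p-values and labels."""
    return _load("mirna_promoter_dm_reference.tsv")
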