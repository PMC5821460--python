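"""Confidence classification of IP-MS interactors.

Post-processes unique-peptide-count tables from duplicate sequential
co-immunoprecipitations (bait V5 channel plus matched IgG isotype
control, two independent experiments):

* a minimum-unique-peptide filter (default >= 2 in at least one bait
  channel);
* a per-experiment exclusivity rule (bait hits with an empty matched
  IgG channel);
* the four-way confidence classification:

  - **red** — found in both experiments, IgG empty in both (high
    confidence);
  - **orange** — found in both experiments, IgG hits in at least one
    (possible interactor);
  - **yellow** — found in exactly one experiment, IgG empty in both
    (low confidence);
  - **gray** — everything else (background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import PeptideTable

__all__ = [
    "filter_min_unique",
    "exclusive_interactors",
    "classify_confidence",
    "InteractorReport",
    "CLASSES",
]

CLASSES = ("red", "orange", "yellow", "gray")


def filter_min_unique(table: PeptideTable, min_unique: int = 2,
                      per_experiment: bool = False) -> PeptideTable:
    """Keep proteins with >= ``min_unique`` unique peptides in a bait channel.

    By default the minimum applies to at least one V5 channel overall;
    ``per_experiment=True`` applies it strictly to every experiment in
    which the protein is counted as found.
    """
    df = table.rows
    if len(df) == 0:
        return PeptideTable(df.copy())
    v1 = df["V5_1"].to_numpy(int)
    v2 = df["V5_2"].to_numpy(int)
    if per_experiment:
        keep = ((v1 >= min_unique) | (v1 == 0)) & ((v2 >= min_unique) | (v2 == 0)) \
            & ((v1 >= min_unique) | (v2 >= min_unique))
    else:
        keep = (v1 >= min_unique) | (v2 >= min_unique)
    return PeptideTable(df.loc[keep].reset_index(drop=True))


def exclusive_interactors(table: PeptideTable, experiment: int) -> set[str]:
    """Proteins found in the bait IP of one experiment with an empty
    matched IgG control (components of the bait complex)."""
    if experiment not in (1, 2):
        raise ValueError("experiment must be 1 or 2")
    df = table.rows
    if len(df) == 0:
        return set()
    v = df[f"V5_{experiment}"].to_numpy(int)
    g = df[f"IgG_{experiment}"].to_numpy(int)
    return set(df.loc[(v > 0) & (g == 0), "protein_id"])


@dataclass
class InteractorReport:
    """Per-protein confidence classes plus per-experiment exclusive counts."""

    classified: pd.DataFrame        # protein_id, counts, class
    exclusive_counts: tuple[int, int]

    def class_counts(self) -> pd.Series:
        return (
            self.classified["class"].value_counts().reindex(CLASSES, fill_value=0)
        )

    def summary(self) -> str:
        cc = self.class_counts()
        lines = [
            "IP-MS interactor classification",
            "=" * 40,
            f"proteins classified:       {len(self.classified)}",
            f"red (high confidence):     {cc['red']}",
            f"orange (possible):         {cc['orange']}",
            f"yellow (low confidence):   {cc['yellow']}",
            f"gray (background):         {cc['gray']}",
            f"exclusive, experiment 1:   {self.exclusive_counts[0]}",
            f"exclusive, experiment 2:   {self.exclusive_counts[1]}",
        ]
        return "\n".join(lines)


def classify_confidence(table: PeptideTable) -> InteractorReport:
    """Assign every protein of a (filtered) peptide table one class.

    Presence in an experiment means >= 1 unique peptide in that
    experiment's bait (V5) channel; the input is expected to have passed
    :func:`filter_min_unique`. A protein found in a single experiment
    but with IgG peptides is gray (background).
    """
    df = table.rows.copy()
    if len(df) == 0:
        df["class"] = pd.Series(dtype=object)
        return InteractorReport(df, (0, 0))

    v1 = df["V5_1"].to_numpy(int) > 0
    v2 = df["V5_2"].to_numpy(int) > 0
    g1 = df["IgG_1"].to_numpy(int) > 0
    g2 = df["IgG_2"].to_numpy(int) > 0

    both = v1 & v2
    one = v1 ^ v2
    igg_clean = ~g1 & ~g2

    cls = np.full(len(df), "gray", dtype=object)
    cls[both & igg_clean] = "red"
    cls[both & ~igg_clean] = "orange"
    cls[one & igg_clean] = "yellow"
    df["class"] = cls

    excl = (
        len(exclusive_interactors(table, 1)),
        len(exclusive_interactors(table, 2)),
    )
    return InteractorReport(df, excl)
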