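"""Nine-mode cross-stage expression taxonomy.

Each protein gets a two-letter label: its direction at the Healthy->NAT
transition followed by its direction at the NAT->Tumor transition, each of
U (up), D (down) or S (stable).  UD is the tumor-adjacent specific
activation (TASA) pattern: up in NAT vs Healthy, back down in Tumor vs NAT.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import classify_de

log = logging.getLogger(__name__)

MODES = ("SS", "SU", "SD", "US", "UU", "UD", "DU", "DS", "DD")
NON_SS_MODES = tuple(m for m in MODES if m != "SS")


@dataclass(eq=False)
class ModeAssignment:
    """Per-protein mode labels over a common testable universe.

    ``table`` is indexed by protein ID with columns ``label_hn``,
    ``label_nt`` and ``mode`` (their concatenation); ``universe`` lists the
    proteins testable in both transitions; ``n_excluded`` counts proteins
    dropped for being untestable in either table.
    """

    table: pd.DataFrame
    universe: list[str]
    n_excluded: int

    def counts(self) -> dict[str, int]:
        c = self.table["mode"].value_counts()
        return {m: int(c.get(m, 0)) for m in MODES}


def assign_modes(de_hn: pd.DataFrame, de_nt: pd.DataFrame,
                 alpha: float = 0.01, fc_min: float = 1.5,
                 require_fc: bool = False) -> ModeAssignment:
    """Combine the NAT-vs-Healthy and Tumor-vs-NAT differential tables into
    nine modes.

    Both tables must have been produced with identical thresholds if they
    carry them; the direction labels are recomputed here from ``p_adj`` and
    ``log2fc`` with the thresholds given, so both transitions are always
    gated identically.  Proteins missing (or untestable, NaN p) in either
    table are excluded from the universe and counted.
    """
    for de, name in ((de_hn, "healthy_to_nat"), (de_nt, "nat_to_tumor")):
        recorded = {k: de.attrs[k] for k in ("alpha", "fc_min", "require_fc")
                    if k in de.attrs}
        expected = {"alpha": alpha, "fc_min": fc_min, "require_fc": require_fc}
        for k, v in recorded.items():
            if v != expected[k]:
                raise ValueError(
                    f"threshold mismatch in {name} table: {k}={v} vs {expected[k]}")
    shared = de_hn.index.intersection(de_nt.index)
    ok = shared[de_hn.loc[shared, "p_adj"].notna()
                & de_nt.loc[shared, "p_adj"].notna()]
    n_excluded = len(de_hn.index.union(de_nt.index)) - len(ok)
    if n_excluded:
        log.info("assign_modes: %d proteins excluded from mode universe", n_excluded)
    lab_hn = classify_de(de_hn.loc[ok, "p_adj"], de_hn.loc[ok, "log2fc"],
                         alpha, fc_min, require_fc)
    lab_nt = classify_de(de_nt.loc[ok, "p_adj"], de_nt.loc[ok, "log2fc"],
                         alpha, fc_min, require_fc)
    table = pd.DataFrame({"label_hn": lab_hn, "label_nt": lab_nt},
                         index=pd.Index(ok, name="protein_id"))
    table["mode"] = table["label_hn"] + table["label_nt"]
    return ModeAssignment(table, list(ok), n_excluded)


def mode_set(assignment: ModeAssignment, modes) -> list[str]:
    """Proteins carrying the given mode(s); "All" is the union of the eight
    non-SS modes."""
    if isinstance(modes, str):
        modes = [modes]
    expanded: list[str] = []
    for mo in modes:
        if mo == "All":
            expanded.extend(NON_SS_MODES)
        elif mo in MODES:
            expanded.append(mo)
        else:
            raise ValueError(f"unknown mode {mo!r}")
    mask = assignment.table["mode"].isin(expanded)
    return list(assignment.table.index[mask])


def tasa_concordance(assignment: ModeAssignment, tasa_ids) -> pd.DataFrame:
    """Check a list of TASA gene IDs against the assigned modes.

    Returns one row per ID (quantified flag, assigned mode, UD match flag);
    summary counts are in ``df.attrs['n_quantified']`` and
    ``df.attrs['n_matching_ud']``.
    """
    rows = []
    for pid in tasa_ids:
        quantified = pid in assignment.table.index
        mode = assignment.table.loc[pid, "mode"] if quantified else ""
        rows.append((pid, quantified, mode, quantified and mode == "UD"))
    df = pd.DataFrame(rows, columns=["protein_id", "quantified", "mode",
                                     "matches_ud"]).set_index("protein_id")
    df.attrs["n_quantified"] = int(df["quantified"].sum())
    df.attrs["n_matching_ud"] = int(df["matches_ud"].sum())
    return df


def write_mode_table(assignment: ModeAssignment, table_path, summary_path=None) -> None:
    assignment.table.to_csv(table_path, sep="\t")
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump({"counts": assignment.counts(),
                       "n_universe": len(assignment.universe),
                       "n_excluded": assignment.n_excluded},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")
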