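"""Protein–ligand interaction-table profiling.

Tables record, per ligand and binding-site residue, the interaction kinds
observed during docking or LigPlot analysis: ``H`` hydrogen bond, ``Hb``
hydrophobic contact, ``Pi`` π–π stacking.  Per-ligand totals count each
recorded interaction kind (a ``Pi/Hb`` cell contributes two), whereas the
per-residue percentages count ligands — a ligand either interacts with a
residue or it does not, regardless of how many kinds the cell lists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import pandas as pd

KNOWN_KINDS = {"H", "Hb", "Pi"}
_EMPTY_TOKENS = {"", "-", "—", "–"}


class InteractionParseError(ValueError):
    pass


@dataclass
class InteractionTable:
    ligands: list[str]
    residues: list[str]
    cells: dict[tuple[str, str], frozenset]  # (ligand, residue) -> kinds

    def __post_init__(self) -> None:
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("residue labels must be unique")

    def kinds(self, ligand: str, residue: str) -> frozenset:
        return self.cells.get((ligand, residue), frozenset())

    def interacting_residues(self, ligand: str) -> set[str]:
        return {r for r in self.residues if self.kinds(ligand, r)}


def _parse_cell(token, ligand: str, residue: str) -> frozenset:
    token = str(token).strip()
    if token in _EMPTY_TOKENS or token.lower() == "nan":
        return frozenset()
    kinds = set()
    for part in token.split("/"):
        part = part.strip()
        if part not in KNOWN_KINDS:
            raise InteractionParseError(
                f"unknown interaction kind {part!r} at ({ligand}, {residue})"
            )
        kinds.add(part)
    return frozenset(kinds)


def read_interactions(path) -> InteractionTable:
    """CSV: first column ligand names, remaining columns residue labels;
    cells are ``-``/``—`` (none) or slash-joined kinds such as ``Pi/Hb``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    with open(path) as fh:
        header = next(csv.reader(fh))
    if len(set(header[1:])) != len(header[1:]):
        raise ValueError("residue labels must be unique")
    ligand_col = df.columns[0]
    residues = list(df.columns[1:])
    ligands = list(df[ligand_col])
    cells = {}
    for _, row in df.iterrows():
        for res in residues:
            kinds = _parse_cell(row[res], row[ligand_col], res)
            if kinds:
                cells[(row[ligand_col], res)] = kinds
    return InteractionTable(ligands=ligands, residues=residues, cells=cells)


def bundled_interactions() -> InteractionTable:
    """The packaged FKBP52 docking-interaction table (control + three
    candidates over ten binding-site residues)."""
    from importlib import resources

    with resources.as_file(
        resources.files("fkbpscreen.data").joinpath("table2_interactions.csv")
    ) as p:
        return read_interactions(p)


def ligand_totals(table: InteractionTable) -> dict[str, int]:
    """Total recorded interactions per ligand, counting every kind in a
    cell (so a ``Pi/Hb`` cell adds two)."""
    if not table.ligands:
        raise ValueError("empty interaction table")
    return {
        lig: sum(len(table.kinds(lig, res)) for res in table.residues)
        for lig in table.ligands
    }


def ligand_residue_counts(table: InteractionTable) -> dict[str, int]:
    """Number of distinct residues each ligand interacts with."""
    if not table.ligands:
        raise ValueError("empty interaction table")
    return {lig: len(table.interacting_residues(lig)) for lig in table.ligands}


def residue_percentages(table: InteractionTable) -> dict[str, float]:
    """Percentage of ligands interacting with each residue (denominator:
    all ligands in the table, control included)."""
    n = len(table.ligands)
    if n == 0:
        raise ValueError("empty interaction table")
    return {
        res: 100.0 * sum(1 for lig in table.ligands if table.kinds(lig, res)) / n
        for res in table.residues
    }


def compare_to_control(table: InteractionTable, control: str) -> dict[str, dict]:
    """Residue-set algebra per candidate vs. the control ligand:
    shared / candidate-only / control-only interacting residues."""
    if control not in table.ligands:
        raise KeyError(f"control ligand {control!r} not in table")
    control_set = table.interacting_residues(control)
    out = {}
    for lig in table.ligands:
        if lig == control:
            continue
        lig_set = table.interacting_residues(lig)
        out[lig] = {
            "shared": sorted(lig_set & control_set),
            "candidate_only": sorted(lig_set - control_set),
            "control_only": sorted(control_set - lig_set),
        }
    return out


def profile(table: InteractionTable, control: str | None = None) -> dict:
    """Full report: totals, percentages and (optionally) the control
    comparison, as plain JSON-serializable data."""
    report = {
        "ligand_totals": ligand_totals(table),
        "residue_percentages": residue_percentages(table),
    }
    if control is not None:
        report["vs_control"] = compare_to_control(table, control)
    return report
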