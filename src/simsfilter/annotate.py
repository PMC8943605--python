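"""Compound-database annotation and DBE-versus-carbon-number tables.

Supports the three annotation routes used on serum-like samples:
bulk-lipid matching against a formula/class database, a combinatorial
database of short peptides built from canonical amino-acid residue
formulas, and (via the generic matcher) salt-composition searches.
Matching is exact on the neutral molecular formula after adduct
arithmetic — never on mass — so a database hit means the enumerated ion
composition corresponds exactly to a known compound under one of the
allowed ionization routes ([M+H]+, [M+Na]+, [M-H]-, or the intact
radical/even-electron species).

The bundled ``lipids_demo_synthetic.csv`` is a small hand-built
stand-in subset of bulk lipid formulas (formula + class + name) for
demos and tests; real analyses should load a full database export with
:func:`load_database`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from itertools import combinations_with_replacement
from pathlib import Path

import pandas as pd

from .chem import (
    DEFAULT_ELEMENTS,
    ElementTable,
    MolecularFormula,
    format_formula,
    parse_formula,
)
from .engine import AssignmentSet

__all__ = [
    "CompoundRecord",
    "CompoundDatabase",
    "DbMatch",
    "load_database",
    "bundled_lipid_database",
    "match_database",
    "build_peptide_database",
    "AMINO_ACID_RESIDUES",
    "dbe_vs_carbon_table",
    "plot_dbe_vs_carbon",
]

#: Adduct name -> (formula delta from neutral to ion, polarity)
_ADDUCTS: dict[str, tuple[MolecularFormula, str | None]] = {
    "+H": (parse_formula("H"), "positive"),
    "+Na": (parse_formula("Na"), "positive"),
    "-H": (parse_formula("H"), "negative"),
    "none": (MolecularFormula(), None),
}


def _canon_adduct(name: str) -> str:
    name = name.replace("−", "-").strip()  # unicode minus
    if name not in _ADDUCTS:
        raise ValueError(f"unknown adduct {name!r}; allowed: {sorted(_ADDUCTS)}")
    return name


@dataclass(frozen=True)
class CompoundRecord:
    """A neutral compound: molecular formula, class label, optional name."""

    formula: MolecularFormula
    class_label: str
    name: str | None = None

    def __post_init__(self) -> None:
        if len(self.formula) == 0:
            raise ValueError("compound formula must be non-empty")


@dataclass(frozen=True)
class DbMatch:
    """One database hit for a candidate ion, with the adduct that produced it."""

    record: CompoundRecord
    adduct: str


class CompoundDatabase:
    """Formula-indexed compound records; isomers sharing a formula are all
    kept and all returned on lookup."""

    def __init__(self, records: list[CompoundRecord] | None = None):
        self.records: list[CompoundRecord] = list(records or [])
        self._index: dict[MolecularFormula, list[CompoundRecord]] = {}
        for rec in self.records:
            self._index.setdefault(rec.formula, []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, formula: MolecularFormula) -> list[CompoundRecord]:
        return list(self._index.get(formula, []))

    def n_distinct_formulas(self) -> int:
        return len(self._index)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["formula", "class", "name"])
            for rec in self.records:
                writer.writerow(
                    [format_formula(rec.formula), rec.class_label, rec.name or ""]
                )


def load_database(path: str | Path) -> CompoundDatabase:
    """Load a compound database CSV (columns: formula, class, optional name).

    Malformed formulas are reported with their row number; an empty file
    yields an empty database with a warning.
    """
    records: list[CompoundRecord] = []
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "formula" not in reader.fieldnames:
            if reader.fieldnames is None:
                warnings.warn(f"{path}: empty database file", stacklevel=2)
                return CompoundDatabase()
            raise ValueError(f"{path}: missing 'formula' column")
        for i, row in enumerate(reader, start=2):
            try:
                formula = parse_formula(row["formula"])
            except ValueError as exc:
                errors.append(f"row {i}: {exc}")
                continue
            records.append(
                CompoundRecord(
                    formula=formula,
                    class_label=(row.get("class") or "").strip(),
                    name=(row.get("name") or "").strip() or None,
                )
            )
    if errors:
        raise ValueError(f"{path}: malformed formulas — " + "; ".join(errors))
    if not records:
        warnings.warn(f"{path}: empty database file", stacklevel=2)
    return CompoundDatabase(records)


def bundled_lipid_database() -> CompoundDatabase:
    """The small synthetic stand-in lipid database shipped with the package."""
    ref = resources.files("simsfilter.data") / "lipids_demo_synthetic.csv"
    with resources.as_file(ref) as path:
        return load_database(path)


def match_database(
    aset: AssignmentSet,
    db: CompoundDatabase,
    adducts=("+H", "+Na"),
    polarity: str | None = None,
) -> AssignmentSet:
    """Annotate candidates with database hits reachable via the adduct set.

    For each candidate ion composition and each allowed adduct the
    neutral formula is reconstructed (subtract the adduct atom for +H/+Na,
    add back the transferred proton for -H, identity for 'none') and
    looked up exactly. Adducts that would drive a count negative are
    skipped silently. Hits land in ``CandidateAssignment.db_matches`` as
    :class:`DbMatch` tuples; the assignment structure is otherwise
    untouched.
    """
    pol = polarity or aset.polarity
    names = [_canon_adduct(a) for a in adducts]
    if pol is not None:
        bad = [a for a in names if _ADDUCTS[a][1] not in (None, pol)]
        if bad:
            raise ValueError(f"adducts {bad} inconsistent with polarity {pol!r}")

    out = AssignmentSet(unassigned=list(aset.unassigned), polarity=aset.polarity)
    for pid, cands in aset.candidates.items():
        annotated = []
        for cand in cands:
            hits: list[DbMatch] = []
            for adduct in names:
                delta, _ = _ADDUCTS[adduct]
                try:
                    if adduct == "-H":
                        neutral = cand.formula + delta
                    else:
                        neutral = cand.formula - delta
                except ValueError:
                    continue  # adduct subtraction went negative
                if len(neutral) == 0:
                    continue
                for rec in db.lookup(neutral):
                    hits.append(DbMatch(record=rec, adduct=adduct))
            annotated.append(replace(cand, db_matches=tuple(hits)))
        out.candidates[pid] = annotated
    return out


def _load_residues() -> list[tuple[str, MolecularFormula]]:
    ref = resources.files("simsfilter.data") / "amino_acids.csv"
    with resources.as_file(ref) as path, open(path, newline="") as fh:
        return [
            (row["letter"], parse_formula(row["residue_formula"]))
            for row in csv.DictReader(fh)
        ]


#: letter -> residue formula (amino acid minus H2O) for the 20 canonical
#: amino acids; leucine and isoleucine share C6H11NO.
AMINO_ACID_RESIDUES: dict[str, MolecularFormula] = dict(_load_residues())

_WATER = parse_formula("H2O")


def build_peptide_database(max_residues: int) -> CompoundDatabase:
    """Combinatorial database of peptides of 1..max_residues residues.

    One record per residue *multiset* (composition, not sequence) over
    the 20 canonical residues; the neutral peptide formula is the sum of
    residue formulas plus one water. Distinct multisets sharing a
    formula (e.g. any Leu/Ile swap) are all retained, and the class
    label stores the sorted residue letters. Record count follows the
    multiset closed form sum_k C(19+k, k): 20 at max_residues=1,
    230,229 at 6. Sizes above 6 are allowed but warned about.
    """
    if max_residues < 1:
        raise ValueError("max_residues must be >= 1")
    if max_residues > 6:
        warnings.warn(
            f"max_residues={max_residues}: database size grows combinatorially",
            stacklevel=2,
        )
    letters = list(AMINO_ACID_RESIDUES)
    residue_counts = [dict(AMINO_ACID_RESIDUES[aa]) for aa in letters]
    records: list[CompoundRecord] = []
    for k in range(1, max_residues + 1):
        for combo in combinations_with_replacement(range(len(letters)), k):
            counts = {"H": 2, "O": 1}  # start from the terminal water
            for idx in combo:
                for sym, n in residue_counts[idx].items():
                    counts[sym] = counts.get(sym, 0) + n
            records.append(
                CompoundRecord(
                    formula=MolecularFormula(counts),
                    class_label="peptide",
                    name="".join(letters[i] for i in combo),
                )
            )
    return CompoundDatabase(records)


def dbe_vs_carbon_table(
    aset: AssignmentSet,
    dbe_convention: str = "ion",
    peaklist=None,
    table: ElementTable = DEFAULT_ELEMENTS,
) -> pd.DataFrame:
    """One row per (peak, candidate) with carbon number and DBE.

    ``dbe_convention='ion'`` (default) keeps the half-integer values of
    [M±H] ion compositions; ``'neutral'`` shifts by ±0.5 according to
    the assignment's polarity. Intensity is carried through (when a
    peak list is supplied) for marker sizing; the class column holds the
    first database match label, if any.
    """
    if dbe_convention not in ("ion", "neutral"):
        raise ValueError("dbe_convention must be 'ion' or 'neutral'")
    shift = 0.0
    if dbe_convention == "neutral":
        if aset.polarity not in ("positive", "negative"):
            raise ValueError("neutral convention requires assignment polarity")
        shift = 0.5 if aset.polarity == "positive" else -0.5
    mz_of, inten_of = {}, {}
    if peaklist is not None:
        for p in peaklist.peaks:
            mz_of[p.id] = p.mz
            inten_of[p.id] = p.total_intensity
    rows = []
    for pid, cands in aset.candidates.items():
        for cand in cands:
            label = cand.db_matches[0].record.class_label if cand.db_matches else ""
            rows.append(
                {
                    "peak_id": pid,
                    "mz": mz_of.get(pid, cand.theoretical_mz),
                    "formula": format_formula(cand.formula),
                    "C": cand.carbon_number,
                    "DBE": cand.dbe_value + shift,
                    "intensity": inten_of.get(pid, float("nan")),
                    "class": label,
                }
            )
    return pd.DataFrame(
        rows, columns=["peak_id", "mz", "formula", "C", "DBE", "intensity", "class"]
    )


def plot_dbe_vs_carbon(
    table: pd.DataFrame, path: str | Path, dbe_convention: str = "ion"
):
    """Scatter DBE against carbon number, marker area scaled by intensity.

    Thin layer over :func:`dbe_vs_carbon_table`; the convention used is
    annotated on the axis label so half-integer ion values are never
    mistaken for neutral ones.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    inten = table["intensity"].to_numpy(dtype=float)
    if len(inten) and pd.notna(inten).any() and inten[pd.notna(inten)].max() > 0:
        size = 10 + 90 * inten / inten[pd.notna(inten)].max()
    else:
        size = 30.0
    classes = table["class"].fillna("") if len(table) else pd.Series(dtype=str)
    for label in sorted(set(classes)) if len(table) else [""]:
        sel = classes == label
        ax.scatter(
            table.loc[sel, "C"],
            table.loc[sel, "DBE"],
            s=size[sel.to_numpy()] if hasattr(size, "__len__") else size,
            alpha=0.6,
            label=label or None,
        )
    ax.set_xlabel("carbon number")
    ax.set_ylabel(f"DBE ({dbe_convention} convention)")
    if len(table) and any(c for c in classes):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
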