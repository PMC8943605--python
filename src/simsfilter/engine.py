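"""Molecular formula prediction: candidate enumeration under constraints.

Given an observed m/z, a per-element count box and a piecewise ppm
tolerance, enumerate every elemental composition whose theoretical ion
m/z lands within tolerance. The search is a recursive per-element
descent ordered by decreasing element mass with residual-mass bounds
pruning — exact (identical to brute-force Cartesian enumeration) but
fast enough for boxes like C<=100 / H<=200 at m/z up to 2250.

Chemistry plausibility heuristics (non-negative ring-double-bond count,
the nitrogen rule, element-ratio rules) are deliberately opt-in flags:
the default pipeline filters only by composition ranges and ppm error,
and uses DBE downstream for visualization rather than rejection.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .chem import (
    DEFAULT_ELEMENTS,
    ELECTRON_MASS,
    ElementTable,
    MolecularFormula,
    dbe,
    format_formula,
    monoisotopic_mass,
    ppm_error,
)

__all__ = [
    "ElementRange",
    "TolerancePolicy",
    "DEFAULT_TOLERANCE",
    "SearchConstraints",
    "CandidateAssignment",
    "AssignmentSet",
    "tolerance_for",
    "enumerate_candidates",
    "assign_peaklist",
    "filter_unique",
]


@dataclass(frozen=True)
class ElementRange:
    """Allowed count range for one element; ``max_count=None`` means
    mass-bounded (capped at the largest count that can fit under the
    upper mass window at search time)."""

    symbol: str
    min_count: int = 0
    max_count: int | None = None

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError(f"min_count of {self.symbol!r} must be >= 0")
        if self.max_count is not None and self.max_count < self.min_count:
            raise ValueError(f"max_count < min_count for {self.symbol!r}")


@dataclass(frozen=True)
class TolerancePolicy:
    """Piecewise-constant ppm tolerance over m/z.

    ``segments`` is an ordered list of ``(upper_mz, ppm)`` pairs; the last
    segment must have ``upper_mz=None`` (open-ended). An m/z exactly at a
    breakpoint belongs to the higher-m/z segment, so with the default
    policy m/z 95.0 gets the tighter 2 ppm.
    """

    segments: tuple[tuple[float | None, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("tolerance policy needs at least one segment")
        if self.segments[-1][0] is not None:
            raise ValueError("last tolerance segment must be open-ended (None)")
        bounds = [b for b, _ in self.segments[:-1]]
        if any(b is None for b in bounds):
            raise ValueError("only the last segment may be open-ended")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("tolerance breakpoints must strictly increase")
        if any(ppm <= 0 for _, ppm in self.segments):
            raise ValueError("ppm tolerances must be positive")

    @classmethod
    def constant(cls, ppm: float) -> "TolerancePolicy":
        return cls(((None, ppm),))

    @classmethod
    def from_pairs(cls, pairs) -> "TolerancePolicy":
        return cls(tuple((None if b is None else float(b), float(p)) for b, p in pairs))


#: 3 ppm below m/z 95, 2 ppm at and above — typical Orbitrap-SIMS errors.
DEFAULT_TOLERANCE = TolerancePolicy.from_pairs([(95.0, 3.0), (None, 2.0)])


def tolerance_for(mz: float, policy: TolerancePolicy = DEFAULT_TOLERANCE) -> float:
    """ppm tolerance of the policy segment containing ``mz``."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    for upper, ppm in policy.segments:
        if upper is None or mz < upper:
            return ppm
    raise AssertionError("unreachable: last segment is open-ended")


@dataclass(frozen=True)
class SearchConstraints:
    """A formula-prediction search: element box + tolerance + charge.

    ``charge`` is +1/-1 for ion searches (electron mass applied) or 0 to
    match neutral monoisotopic mass directly.
    """

    ranges: tuple[ElementRange, ...]
    tolerance: TolerancePolicy = DEFAULT_TOLERANCE
    charge: int = -1

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("at least one element range required")
        symbols = [r.symbol for r in self.ranges]
        if len(set(symbols)) != len(symbols):
            raise ValueError("duplicate element symbols in ranges")
        if self.charge not in (-1, 0, 1):
            raise ValueError("charge must be -1, 0 or +1")

    @property
    def polarity(self) -> str | None:
        return {1: "positive", -1: "negative", 0: None}[self.charge]

    # -- JSON config ------------------------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict) -> "SearchConstraints":
        ranges = tuple(
            ElementRange(sym, int(lo), None if hi is None else int(hi))
            for sym, (lo, hi) in cfg["elements"].items()
        )
        tol = (
            TolerancePolicy.from_pairs(cfg["tolerance"])
            if "tolerance" in cfg
            else DEFAULT_TOLERANCE
        )
        if "charge" in cfg:
            charge = int(cfg["charge"])
        elif "polarity" in cfg:
            charge = {"positive": 1, "negative": -1, "neutral": 0}[cfg["polarity"]]
        else:
            charge = -1
        return cls(ranges=ranges, tolerance=tol, charge=charge)

    @classmethod
    def from_json(cls, path: str | Path) -> "SearchConstraints":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "elements": {r.symbol: [r.min_count, r.max_count] for r in self.ranges},
            "tolerance": [list(seg) for seg in self.tolerance.segments],
            "charge": self.charge,
        }


@dataclass(frozen=True)
class CandidateAssignment:
    """One peak <-> formula candidate with its diagnostics."""

    peak_id: str
    formula: MolecularFormula
    theoretical_mz: float
    error_ppm: float
    dbe_value: float
    carbon_number: int
    unique: bool = False
    db_matches: tuple = ()  # filled by annotate.match_database


@dataclass
class AssignmentSet:
    """Per-peak candidate lists plus the unassigned remainder.

    Every input peak appears exactly once: either as a key of
    ``candidates`` (with a non-empty list) or in ``unassigned``.
    """

    candidates: dict[str, list[CandidateAssignment]] = field(default_factory=dict)
    unassigned: list[str] = field(default_factory=list)
    polarity: str | None = None

    @property
    def assigned_ids(self) -> list[str]:
        return list(self.candidates)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.candidates) + list(self.unassigned)

    def n_candidates(self, peak_id: str) -> int:
        return len(self.candidates.get(peak_id, []))

    def to_dataframe(self, peaklist=None) -> pd.DataFrame:
        """Flatten to one row per (peak, candidate); unassigned peaks get a
        single row with an empty formula. Column order matches the TSV
        contract (peak_id, mz, intensity, formula, theoretical_mz, ppm,
        DBE, C_number, n_candidates, unique)."""
        mz_of, inten_of = {}, {}
        if peaklist is not None:
            for p in peaklist.peaks:
                mz_of[p.id] = p.mz
                inten_of[p.id] = p.total_intensity
        rows = []
        for pid, cands in self.candidates.items():
            for c in cands:
                rows.append(
                    {
                        "peak_id": pid,
                        "mz": mz_of.get(pid, float("nan")),
                        "intensity": inten_of.get(pid, float("nan")),
                        "formula": format_formula(c.formula),
                        "theoretical_mz": c.theoretical_mz,
                        "ppm": c.error_ppm,
                        "DBE": c.dbe_value,
                        "C_number": c.carbon_number,
                        "n_candidates": len(cands),
                        "unique": c.unique,
                    }
                )
        for pid in self.unassigned:
            rows.append(
                {
                    "peak_id": pid,
                    "mz": mz_of.get(pid, float("nan")),
                    "intensity": inten_of.get(pid, float("nan")),
                    "formula": "",
                    "theoretical_mz": float("nan"),
                    "ppm": float("nan"),
                    "DBE": float("nan"),
                    "C_number": -1,
                    "n_candidates": 0,
                    "unique": False,
                }
            )
        columns = [
            "peak_id",
            "mz",
            "intensity",
            "formula",
            "theoretical_mz",
            "ppm",
            "DBE",
            "C_number",
            "n_candidates",
            "unique",
        ]
        return pd.DataFrame(rows, columns=columns)

    def write_tsv(self, path: str | Path, peaklist=None) -> None:
        self.to_dataframe(peaklist).to_csv(path, sep="\t", index=False)


def _candidate_from_counts(
    peak_id: str,
    mz: float,
    counts: dict[str, int],
    charge: int,
    table: ElementTable,
) -> CandidateAssignment:
    formula = MolecularFormula(counts)
    mass = monoisotopic_mass(formula, table)
    theo = mass - charge * ELECTRON_MASS if charge else mass
    carbon = sum(n for s, n in formula.items() if table[s].dbe_class == "carbon")
    return CandidateAssignment(
        peak_id=peak_id,
        formula=formula,
        theoretical_mz=theo,
        error_ppm=ppm_error(mz, theo),
        dbe_value=dbe(formula, table) if len(formula) else float("nan"),
        carbon_number=carbon,
    )


def enumerate_candidates(
    mz: float,
    constraints: SearchConstraints,
    table: ElementTable = DEFAULT_ELEMENTS,
    peak_id: str = "",
    require_nonneg_dbe: bool = False,
    require_nitrogen_rule: bool = False,
) -> list[CandidateAssignment]:
    """All compositions within tolerance of ``mz`` inside the element box.

    Returns candidates sorted by \\|ppm error\\| with ties broken by the
    formula string, so the ordering is fully reproducible. The optional
    plausibility flags drop candidates with a negative ring-double-bond
    count or (for even-electron neutrals) an odd-nitrogen nominal-mass
    violation; both are off by default.
    """
    if mz <= 0 or not math.isfinite(mz):
        raise ValueError("m/z must be positive and finite")
    tol = tolerance_for(mz, constraints.tolerance)
    z = constraints.charge
    # composition-mass window: ion m/z window shifted by z electron masses
    m_lo = mz * (1 - tol * 1e-6) + z * ELECTRON_MASS
    m_hi = mz * (1 + tol * 1e-6) + z * ELECTRON_MASS

    # resolve mass-bounded maxima and order by decreasing element mass
    resolved: list[tuple[str, float, int, int]] = []
    for r in constraints.ranges:
        em = table[r.symbol].monoisotopic_mass
        hi = r.max_count if r.max_count is not None else int(m_hi // em)
        hi = min(hi, int(m_hi // em))
        if hi < r.min_count:
            return []  # even the minimum count overshoots the window
        resolved.append((r.symbol, em, r.min_count, hi))
    resolved.sort(key=lambda t: -t[1])

    n = len(resolved)
    suffix_min = [0.0] * (n + 1)
    suffix_max = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        _, em, lo, hi = resolved[i]
        suffix_min[i] = suffix_min[i + 1] + lo * em
        suffix_max[i] = suffix_max[i + 1] + hi * em

    out: list[CandidateAssignment] = []
    counts: dict[str, int] = {}

    def descend(i: int, acc: float) -> None:
        if i == n:
            if m_lo <= acc <= m_hi and any(counts.values()):
                out.append(_candidate_from_counts(peak_id, mz, counts, z, table))
            return
        sym, em, lo, hi = resolved[i]
        for c in range(lo, hi + 1):
            new = acc + c * em
            if new + suffix_min[i + 1] > m_hi:
                break  # heavier counts only overshoot further
            if new + suffix_max[i + 1] < m_lo:
                continue
            counts[sym] = c
            descend(i + 1, new)
        counts.pop(sym, None)

    descend(0, 0.0)

    if require_nonneg_dbe:
        out = [c for c in out if c.dbe_value >= 0]
    if require_nitrogen_rule:
        out = [c for c in out if _nitrogen_rule_ok(c.formula, table)]
    out.sort(key=lambda c: (abs(c.error_ppm), format_formula(c.formula)))
    return out


def _nitrogen_rule_ok(formula: MolecularFormula, table: ElementTable) -> bool:
    """Even nominal mass <-> even nitrogen count (even-electron neutrals)."""
    nominal = sum(
        n * round(table[s].monoisotopic_mass) for s, n in formula.items()
    )
    n_nitrogen = sum(
        n for s, n in formula.items() if table[s].dbe_class == "nitrogen_group"
    )
    return (nominal % 2) == (n_nitrogen % 2)


def enumerate_candidates_bruteforce(
    mz: float,
    constraints: SearchConstraints,
    table: ElementTable = DEFAULT_ELEMENTS,
    peak_id: str = "",
) -> list[CandidateAssignment]:
    """Reference oracle: full Cartesian product, no pruning.

    Only usable for small boxes; exists so tests can prove the pruned
    search is exact. ``max_count=None`` is resolved the same way as in
    :func:`enumerate_candidates`.
    """
    tol = tolerance_for(mz, constraints.tolerance)
    z = constraints.charge
    m_lo = mz * (1 - tol * 1e-6) + z * ELECTRON_MASS
    m_hi = mz * (1 + tol * 1e-6) + z * ELECTRON_MASS
    axes = []
    symbols = []
    for r in constraints.ranges:
        em = table[r.symbol].monoisotopic_mass
        hi = r.max_count if r.max_count is not None else int(m_hi // em)
        hi = min(hi, int(m_hi // em))
        if hi < r.min_count:
            return []
        symbols.append(r.symbol)
        axes.append(range(r.min_count, hi + 1))
    out = []
    for combo in itertools.product(*axes):
        if not any(combo):
            continue
        mass = sum(c * table[s].monoisotopic_mass for s, c in zip(symbols, combo))
        if m_lo <= mass <= m_hi:
            out.append(
                _candidate_from_counts(
                    peak_id, mz, dict(zip(symbols, combo)), z, table
                )
            )
    out.sort(key=lambda c: (abs(c.error_ppm), format_formula(c.formula)))
    return out


def assign_peaklist(
    peaklist,
    constraints: SearchConstraints,
    table: ElementTable = DEFAULT_ELEMENTS,
    **flags,
) -> AssignmentSet:
    """Run :func:`enumerate_candidates` on every peak of a PeakList."""
    aset = AssignmentSet(polarity=constraints.polarity)
    for peak in peaklist.peaks:
        cands = enumerate_candidates(
            peak.mz, constraints, table=table, peak_id=peak.id, **flags
        )
        if cands:
            if len(cands) == 1:
                cands = [replace(cands[0], unique=True)]
            aset.candidates[peak.id] = cands
        else:
            aset.unassigned.append(peak.id)
    return aset


def filter_unique(aset: AssignmentSet) -> AssignmentSet:
    """Keep only peaks with exactly one candidate within tolerance.

    Multi-candidate peaks move to the unassigned side of the filtered
    view; survivors are flagged ``unique=True``.
    """
    out = AssignmentSet(polarity=aset.polarity)
    for pid, cands in aset.candidates.items():
        if len(cands) == 1:
            out.candidates[pid] = [replace(cands[0], unique=True)]
        else:
            out.unassigned.append(pid)
    out.unassigned.extend(aset.unassigned)
    return out
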