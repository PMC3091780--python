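"""Spike-in panel design: dilution pools and condition panels with exact ground truth.

The core experimental designs are (a) a cyclic Latin-square arrangement of
RNA standards across sample pools, where each standard visits every abundance
level exactly once and every pool carries every level exactly once, so all
pools contain the same total number of spiked transcript copies; and (b) a
pair of single-sample "normal"/"disease" panels in which a subset of
standards changes abundance by a known ratio, giving an exact fold-change
ground truth for differential-expression benchmarking.

Abundances are expressed throughout as transcript copies per nanogram of
total RNA ("copies/ng").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23
#: average molar mass of one ribonucleotide in single-stranded RNA, g/mol
NT_MOLAR_MASS_G = 330.0

__all__ = [
    "RNAStandard",
    "PanelDesign",
    "PanelPair",
    "DesignValidation",
    "DesignError",
    "default_standards",
    "dilution_levels",
    "make_dilution_pools",
    "dilution_pool_design",
    "make_condition_panels",
    "condition_panel_pair",
    "copies_per_cell",
    "expected_copies_per_reaction",
    "spike_mass_fraction",
    "validate_design",
]


class DesignError(ValueError):
    """Raised for structurally invalid panel designs or dosing arithmetic."""


@dataclass(frozen=True)
class RNAStandard:
    """One synthetic RNA standard (an ERCC-style external control transcript).

    Parameters
    ----------
    id : str
        Standard identifier, e.g. ``"ERCC-13"``.
    length_nt : int
        Transcript length in nucleotides; must be positive.
    gc_fraction : float, optional
        GC base fraction in [0, 1], informational only.
    """

    id: str
    length_nt: int
    gc_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.length_nt <= 0:
            raise DesignError(f"standard {self.id!r}: length_nt must be > 0")
        if self.gc_fraction is not None and not 0.0 <= self.gc_fraction <= 1.0:
            raise DesignError(f"standard {self.id!r}: gc_fraction outside [0, 1]")


@dataclass
class PanelDesign:
    """A standards-by-samples dosing matrix of copies/ng total RNA.

    ``copies`` is a DataFrame indexed by standard id with one column per
    sample label; entries are non-negative reals (0 = standard absent).
    """

    standards: list[RNAStandard]
    samples: list[str]
    copies: pd.DataFrame

    def __post_init__(self) -> None:
        ids = [s.id for s in self.standards]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate standard ids in panel")
        if len(set(self.samples)) != len(self.samples):
            raise DesignError("duplicate sample labels in panel")
        self.copies = self.copies.loc[ids, self.samples].astype(float)
        if (self.copies.to_numpy() < 0).any():
            raise DesignError("negative copies/ng in design")
        if len(self.copies) and (self.copies.to_numpy().sum(axis=1) == 0).any():
            dead = self.copies.index[self.copies.sum(axis=1) == 0].tolist()
            raise DesignError(f"standards with no nonzero entry: {dead}")

    @property
    def standard_ids(self) -> list[str]:
        return [s.id for s in self.standards]

    def level_of(self, standard_id: str, sample: str) -> float:
        """Copies/ng of one standard in one sample."""
        return float(self.copies.at[standard_id, sample])

    def lengths(self) -> dict[str, int]:
        return {s.id: s.length_nt for s in self.standards}

    def to_long(self) -> pd.DataFrame:
        """Long-format table with columns standard, sample, copies_per_ng."""
        long = self.copies.rename_axis("standard").reset_index().melt(
            id_vars="standard", var_name="sample", value_name="copies_per_ng"
        )
        return long.sort_values(["standard", "sample"], kind="stable").reset_index(drop=True)


@dataclass
class PanelPair:
    """Two single-sample panels (A = "normal", B = "disease") plus exact truth.

    ``expected_fc`` maps standard id -> copies_B / copies_A, defined for every
    standard dosed in panel A.
    """

    design_A: PanelDesign
    design_B: PanelDesign
    expected_fc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.design_A.samples) != 1 or len(self.design_B.samples) != 1:
            raise DesignError("condition panels must be single-sample designs")
        if self.design_A.standard_ids != self.design_B.standard_ids:
            raise DesignError("panels A and B must share the same standards")

    def truth_frame(self) -> pd.DataFrame:
        """Truth table: standard, copies_A, copies_B, expected_fc."""
        a = self.design_A.copies.iloc[:, 0]
        b = self.design_B.copies.iloc[:, 0]
        return pd.DataFrame(
            {
                "standard": a.index,
                "copies_A": a.to_numpy(),
                "copies_B": b.to_numpy(),
                "expected_fc": [self.expected_fc[s] for s in a.index],
            }
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Default library: the eight standards used throughout, with representative
# (synthetic) lengths spanning the library's 481-1324 nt range.  Per-standard
# lengths are not part of the printed designs, so these are stand-ins chosen
# once for dosing arithmetic.
# ---------------------------------------------------------------------------

_DEFAULT_LENGTHS = {
    "ERCC-13": 523,
    "ERCC-42": 481,
    "ERCC-81": 717,
    "ERCC-84": 683,
    "ERCC-95": 521,
    "ERCC-99": 1324,
    "ERCC-113": 609,
    "ERCC-171": 1023,
}


def default_standards() -> list[RNAStandard]:
    """The eight-standard default library, in canonical (pool-design) row order."""
    return [RNAStandard(i, n) for i, n in _DEFAULT_LENGTHS.items()]


def dilution_levels() -> list[float]:
    """Canonical pool abundance ladder: 0 then seven decades 1..1e6 copies/ng."""
    return [0.0] + [10.0**k for k in range(7)]


def make_dilution_pools(
    standards: list[RNAStandard], levels: list[float]
) -> PanelDesign:
    """Cyclic Latin-square dilution pools.

    Standard at row ``i`` receives, in sample ``j`` (both 0-based),
    ``levels[(j - i + 1) % n]`` — the phase that reproduces the canonical
    eight-standard pool table when given the default standards and the
    ladder ``(0, 1, 10, ..., 1e6)``.  Every standard takes each level exactly
    once across samples, every sample carries each level exactly once, and
    all sample totals are equal (1,111,111 copies/ng for the default ladder).

    Raises
    ------
    DesignError
        If ``len(standards) != len(levels)`` or the levels are not distinct
        non-negative numbers.
    """
    n = len(standards)
    if n != len(levels):
        raise DesignError(
            f"need as many levels as standards (got {n} standards, {len(levels)} levels)"
        )
    lv = [float(x) for x in levels]
    if len(set(lv)) != n:
        raise DesignError("levels must be distinct")
    if any(x < 0 for x in lv):
        raise DesignError("levels must be non-negative")
    samples = [f"pool{j + 1}" for j in range(n)]
    grid = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            grid[i, j] = lv[(j - i + 1) % n]
    copies = pd.DataFrame(grid, index=[s.id for s in standards], columns=samples)
    return PanelDesign(standards=list(standards), samples=samples, copies=copies)


def dilution_pool_design() -> PanelDesign:
    """The canonical 8x8 pool design (default standards, ladder 0..1e6)."""
    return make_dilution_pools(default_standards(), dilution_levels())


def make_condition_panels(
    copies_A: dict[str, float],
    copies_B: dict[str, float],
    standards: list[RNAStandard] | None = None,
) -> PanelPair:
    """Build a normal/disease panel pair with exact expected fold changes.

    ``expected_fc[s] = copies_B[s] / copies_A[s]``; a standard dosed at zero
    in panel A has no finite ratio and is rejected.
    """
    if set(copies_A) != set(copies_B):
        raise DesignError("copies_A and copies_B must cover the same standards")
    undef = sorted(s for s, c in copies_A.items() if c == 0)
    if undef:
        raise DesignError(f"fold change undefined (copies_A = 0) for: {undef}")
    if any(v < 0 for v in copies_A.values()) or any(v < 0 for v in copies_B.values()):
        raise DesignError("copies must be non-negative")
    if standards is None:
        standards = [RNAStandard(s, 1000) for s in copies_A]
    order = [s.id for s in standards]
    if set(order) != set(copies_A):
        raise DesignError("standards do not match the dosing maps")

    def one(name: str, dose: dict[str, float]) -> PanelDesign:
        copies = pd.DataFrame({name: [dose[s] for s in order]}, index=order)
        return PanelDesign(standards=list(standards), samples=[name], copies=copies)

    fc = {s: copies_B[s] / copies_A[s] for s in order}
    return PanelPair(design_A=one("A", copies_A), design_B=one("B", copies_B), expected_fc=fc)


_PANEL_A = {
    "ERCC-13": 1e5,
    "ERCC-42": 1e4,
    "ERCC-81": 1e2,
    "ERCC-84": 1e2,
    "ERCC-95": 1e3,
    "ERCC-99": 8e3,
    "ERCC-113": 1e1,
    "ERCC-171": 1e1,
}
_PANEL_B = {
    "ERCC-13": 1e5,
    "ERCC-42": 5e3,
    "ERCC-81": 1e2,
    "ERCC-84": 5e2,
    "ERCC-95": 1e3,
    "ERCC-99": 1.2e4,
    "ERCC-113": 1e1,
    "ERCC-171": 1e2,
}


def condition_panel_pair() -> PanelPair:
    """The canonical normal/disease panel pair.

    Four standards change between panels (ratios 0.5, 5.0, 1.5 and 10.0) and
    four are unchanged (ratio 1.0), spanning 10 to 1e5 copies/ng.
    """
    return make_condition_panels(_PANEL_A, _PANEL_B, standards=default_standards())


def copies_per_cell(copies_per_ng: float, total_rna_pg_per_cell: float = 26.0) -> float:
    """Convert copies per ng total RNA to copies per cell.

    A mammalian cell holding ``total_rna_pg_per_cell`` picograms of total RNA
    contains ``copies_per_ng * total_rna_pg_per_cell / 1000`` copies.  With
    the 26 pg default, 100 copies/ng is 2.6 copies/cell (commonly rounded to
    order-of-magnitude "1 copy per cell"; this function returns the exact
    product).
    """
    if copies_per_ng < 0 or total_rna_pg_per_cell < 0:
        raise DesignError("copies_per_cell arguments must be non-negative")
    return copies_per_ng * total_rna_pg_per_cell / 1000.0


def expected_copies_per_reaction(copies_per_ng: float, input_ng: float = 1.0) -> float:
    """Expected RNA copies delivered to a reaction with ``input_ng`` ng total RNA.

    At the 1 ng/reaction default, 1 copy/ng equates to 1 expected copy per
    reaction — the regime where Poisson sampling of individual molecules
    dominates detection.
    """
    if copies_per_ng < 0 or input_ng < 0:
        raise DesignError("expected_copies_per_reaction arguments must be non-negative")
    return copies_per_ng * input_ng


def spike_mass_fraction(
    design: PanelDesign,
    mrna_fraction: float = 0.02,
    nt_molar_mass_g: float = NT_MOLAR_MASS_G,
) -> dict[str, float]:
    """Fraction of a sample's mRNA mass contributed by the spiked standards.

    Per sample: ``sum_s copies[s] * length_nt[s] * nt_molar_mass_g / N_A``
    grams of spike per ng of total RNA, divided by ``mrna_fraction`` ng of
    mRNA (mRNA assumed 2% of total RNA by default).  Used to verify that
    spiking does not materially perturb the mRNA content of the sample.
    """
    lengths = design.lengths()
    grams_per_copy = {
        s: lengths[s] * nt_molar_mass_g / AVOGADRO for s in design.standard_ids
    }
    out: dict[str, float] = {}
    for sample in design.samples:
        spike_g = sum(
            design.level_of(s, sample) * grams_per_copy[s] for s in design.standard_ids
        )
        out[sample] = spike_g / (mrna_fraction * 1e-9)
    return out


@dataclass
class DesignValidation:
    """Report from :func:`validate_design`; violations are reported, not raised."""

    is_latin_square: bool | None  # None = not applicable (non-square design)
    equal_column_sums: bool
    sample_totals: dict[str, float]
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (self.is_latin_square is not False) and self.equal_column_sums


def validate_design(design: PanelDesign) -> DesignValidation:
    """Check the Latin-square property and dosing balance of a design.

    For square designs: every standard must take each level exactly once
    across samples and every sample must carry each level exactly once.
    Non-square designs (e.g. single-sample condition panels) report the
    Latin-square check as not applicable.  Column (sample) totals are always
    reported and compared.
    """
    m = design.copies.to_numpy()
    totals = {s: float(design.copies[s].sum()) for s in design.samples}
    msgs: list[str] = []
    n_std, n_samp = m.shape
    if n_std != n_samp or n_std < 2:
        latin: bool | None = None
        msgs.append("Latin-square check not applicable (non-square design)")
    else:
        levels = sorted(m[0, :])
        latin = True
        if len(set(levels)) != n_samp:
            latin = False
            msgs.append("first row does not contain distinct levels")
        else:
            for i in range(n_std):
                if sorted(m[i, :]) != levels:
                    latin = False
                    msgs.append(f"standard {design.standard_ids[i]!r} does not take each level once")
            for j in range(n_samp):
                if sorted(m[:, j]) != levels:
                    latin = False
                    msgs.append(f"sample {design.samples[j]!r} does not carry each level once")
    vals = list(totals.values())
    equal = bool(np.allclose(vals, vals[0])) if vals else True
    if not equal:
        msgs.append("sample totals are not balanced")
    return DesignValidation(
        is_latin_square=latin, equal_column_sums=equal, sample_totals=totals, messages=msgs
    )
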