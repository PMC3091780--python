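"""Synthetic microarray and RT-qPCR data with known ground truth.

Two generators share a :class:`~spikeqc.panels.PanelDesign` dosing matrix:

* ``simulate_microarray`` emits background-corrected probe intensities with a
  saturating (hyperbolic) response, multiplicative lognormal noise whose
  log-scale SD rises at low abundance, shared run and labelling effects, and
  dedicated blank features drawn from a background distribution.
* ``simulate_qpcr`` emits Ct values through explicit Poisson sampling of
  template molecules (dropout when zero molecules are reverse-transcribed),
  a sub-100% RT yield, assay-specific PCR efficiency, Gaussian replicate
  noise on the Ct scale, per-run shifts, and a hard cycle ceiling beyond
  which reactions are reported UNDETERMINED.

Identical (design, params, seed) always reproduce identical tables.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panels import PanelDesign, PanelPair

__all__ = [
    "ArraySimParams",
    "QpcrSimParams",
    "TruthedDataset",
    "SimulationError",
    "simulate_microarray",
    "simulate_qpcr",
    "simulate_panel_pair_microarray",
    "simulate_panel_pair_qpcr",
    "simulate_dilution_qpcr",
    "derive_seed",
    "BLANK",
]

#: standard-id token marking blank (no-target) features
BLANK = "BLANK"
#: standard-id token marking generic background (endogenous-like) features
BACKGROUND = "BACKGROUND"


class SimulationError(ValueError):
    """Raised for non-finite or out-of-domain simulation parameters."""


def derive_seed(seed: int, label: str) -> int:
    """Stable per-stage substream seed (< 2**31) from a top-level seed."""
    return int(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class ArraySimParams:
    """Microarray generator parameters.

    The mean response of a probe for standard *s* at abundance *c* copies/ng
    is ``gain_s * c / (1 + c / saturation_K)`` (hyperbolic compression;
    ``saturation_K = inf`` disables it).  Probe gains are drawn once per
    standard from a lognormal with median ``gain_median`` and log-scale SD
    ``gain_log_sd``; all 100 replicate probes of a standard share one gain
    (identical sequence).  Multiplicative noise is lognormal with log-scale
    variance ``sigma_tech^2 + sigma_low^2 / (1 + c / c0)`` so the CV rises
    from ~sigma_tech at high abundance to ~sqrt(sigma_tech^2+sigma_low^2)
    near zero.  Run and labelling effects are shared lognormal factors.
    Blank features draw from Normal(background_mean, background_sd^2)
    truncated at zero; signal probes are emitted as background-corrected
    values with no additive background term.

    In addition to the spike probes and blanks, each array carries
    ``n_background_features`` generic endogenous-like features standing in
    for the whole-genome probe content of a real array: every background
    feature gets a fixed expression level (lognormal with median
    ``background_feature_median`` and log-scale SD
    ``background_feature_log_sd``), identical in every sample because all
    samples share the same background RNA.  These features anchor the
    75th-percentile normalisation so that per-array scaling does not depend
    on the spike composition of the panel.

    Defaults are calibration choices (documented in the methods note), set so
    the canonical dilution-pool simulation crosses detectability between
    1 and 10 copies/ng with near-complete detection at 100 copies/ng.
    """

    gain_median: float = 50.0  # a.u. per copy/ng
    gain_log_sd: float = 0.5
    background_mean: float = 150.0  # a.u.
    background_sd: float = 30.0  # a.u.
    saturation_K: float = 5e5  # copies/ng; inf = no saturation
    sigma_tech: float = 0.12  # ln-scale SD at high abundance
    sigma_low: float = 1.2  # extra ln-scale SD at low abundance
    c0: float = 5.0  # copies/ng scale of the low-abundance noise term
    run_sd: float = 0.05  # ln-scale SD of run effects
    labelling_sd: float = 0.05  # ln-scale SD of labelling effects
    n_replicate_probes: int = 100
    n_blank_features: int = 100
    n_background_features: int = 600
    background_feature_median: float = 2000.0  # a.u.
    background_feature_log_sd: float = 2.0  # ln-scale spread of expression levels
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_tech", "sigma_low", "run_sd", "labelling_sd", "background_sd"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise SimulationError(f"{name} must be finite and >= 0 (got {v})")
        for name in ("gain_median", "saturation_K", "c0"):
            v = getattr(self, name)
            if math.isnan(v) or v <= 0:
                raise SimulationError(f"{name} must be > 0 (got {v})")
        if not math.isfinite(self.background_mean):
            raise SimulationError("background_mean must be finite")
        if self.n_replicate_probes < 1 or self.n_blank_features < 0:
            raise SimulationError("replicate/blank feature counts out of range")
        if self.n_background_features < 0 or self.background_feature_median <= 0:
            raise SimulationError("background feature parameters out of range")
        if self.background_feature_log_sd < 0:
            raise SimulationError("background_feature_log_sd must be >= 0")


@dataclass
class QpcrSimParams:
    """RT-qPCR generator parameters.

    Per reaction, the number of amplifiable template molecules is
    ``m ~ Poisson(c * reaction_input_ng * rt_yield)``; ``m = 0`` yields
    UNDETERMINED.  Otherwise
    ``Ct = ct_single_molecule - ln(m)/ln(1 + E) + run_shift + N(0, sigma_ct^2)``
    and any Ct above ``max_cycles`` is reported UNDETERMINED.  ``efficiency``
    may be one value for all assays or a per-assay mapping.  With
    ``poisson=False`` the expected molecule count is used exactly (the
    noise-free limit used for closed-form checks).

    The default ``rt_yield`` of 0.25 reflects a reverse-transcription step
    well below 100% efficiency: at 1 expected copy/reaction only
    ``1 - exp(-0.25) ~ 22%`` of reactions fire, and ~92% at 10 copies.
    """

    efficiency: float | dict[str, float] = 0.9
    ct_single_molecule: float = 38.0  # cycles
    sigma_ct: float = 0.25  # cycles
    run_shift_sd: float = 0.3  # cycles
    rt_yield: float = 0.25
    reaction_input_ng: float = 1.0
    max_cycles: int = 45
    n_replicates: int = 3
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        effs = (
            list(self.efficiency.values())
            if isinstance(self.efficiency, dict)
            else [self.efficiency]
        )
        for e in effs:
            if not 0 < e <= 1.2:
                raise SimulationError(f"PCR efficiency must be in (0, 1.2] (got {e})")
        if not 0 < self.rt_yield <= 1:
            raise SimulationError("rt_yield must be in (0, 1]")
        if self.sigma_ct < 0 or self.run_shift_sd < 0:
            raise SimulationError("Ct noise SDs must be >= 0")
        if self.max_cycles <= 0 or self.n_replicates < 1:
            raise SimulationError("max_cycles and n_replicates must be positive")
        if self.reaction_input_ng <= 0:
            raise SimulationError("reaction_input_ng must be > 0")

    def efficiencies_for(self, assays: list[str]) -> dict[str, float]:
        if isinstance(self.efficiency, dict):
            missing = [a for a in assays if a not in self.efficiency]
            if missing:
                raise SimulationError(f"no efficiency given for assays: {missing}")
            return {a: float(self.efficiency[a]) for a in assays}
        return {a: float(self.efficiency) for a in assays}


@dataclass
class TruthedDataset:
    """A simulated dataset bundled with its design, parameters and truth."""

    design: PanelDesign
    params: ArraySimParams | QpcrSimParams
    intensities: pd.DataFrame | None = None
    cts: pd.DataFrame | None = None
    expected_fc: dict[str, float] | None = None
    gains: dict[str, float] | None = None

    def params_dict(self) -> dict:
        return asdict(self.params)


def _draw_gains(design: PanelDesign, params: ArraySimParams) -> dict[str, float]:
    rng = np.random.default_rng(derive_seed(params.seed, "array-gains"))
    g = params.gain_median * np.exp(
        rng.normal(0.0, params.gain_log_sd, size=len(design.standard_ids))
    )
    return dict(zip(design.standard_ids, g))


def simulate_microarray(
    design: PanelDesign,
    params: ArraySimParams | None = None,
    n_runs: int = 3,
    arrays_per_sample_per_run: int = 1,
) -> TruthedDataset:
    """Generate a long-format background-corrected intensity table.

    One array is one (sample, run, labelling) combination; each carries
    ``n_replicate_probes`` probes per standard plus ``n_blank_features``
    blank features.  Standards dosed at 0 copies/ng in a sample draw from the
    blank (background) distribution on that array.

    Returns a :class:`TruthedDataset` whose ``intensities`` frame has columns
    ``feature_id, standard_id, replicate_probe_index, blank, array_id,
    sample, run, labelling_id, raw_intensity``.
    """
    if params is None:
        params = ArraySimParams()
    if n_runs < 1 or arrays_per_sample_per_run < 1:
        raise SimulationError("n_runs and arrays_per_sample_per_run must be >= 1")
    gains = _draw_gains(design, params)
    bg_rng = np.random.default_rng(derive_seed(params.seed, "array-background"))
    # fixed expression level per background feature, shared by every sample
    bg_levels = params.background_feature_median * np.exp(
        bg_rng.normal(0.0, params.background_feature_log_sd, params.n_background_features)
    )
    rng = np.random.default_rng(derive_seed(params.seed, "array-noise"))

    n_probe_rows = len(design.standard_ids) * params.n_replicate_probes
    frames = []
    for run in range(1, n_runs + 1):
        run_eff = math.exp(rng.normal(0.0, params.run_sd))
        for sample in design.samples:
            for rep in range(1, arrays_per_sample_per_run + 1):
                labelling_id = f"{sample}-run{run}-lab{rep}"
                lab_eff = math.exp(rng.normal(0.0, params.labelling_sd))
                array_id = f"{sample}-run{run}-a{rep}"
                std_col, idx_col, raw = [], [], []
                for sid in design.standard_ids:
                    c = design.level_of(sid, sample)
                    npr = params.n_replicate_probes
                    std_col += [sid] * npr
                    idx_col += list(range(1, npr + 1))
                    if c == 0.0:
                        vals = np.maximum(
                            rng.normal(params.background_mean, params.background_sd, npr),
                            0.0,
                        )
                    else:
                        mean = gains[sid] * c / (1.0 + c / params.saturation_K)
                        sd = math.sqrt(
                            params.sigma_tech**2
                            + params.sigma_low**2 / (1.0 + c / params.c0)
                        )
                        vals = mean * np.exp(rng.normal(0.0, sd, npr)) * run_eff * lab_eff
                    raw.append(vals)
                blanks = np.maximum(
                    rng.normal(
                        params.background_mean, params.background_sd, params.n_blank_features
                    ),
                    0.0,
                )
                std_col += [BLANK] * params.n_blank_features
                idx_col += list(range(1, params.n_blank_features + 1))
                raw.append(blanks)
                if params.n_background_features:
                    bg_vals = (
                        bg_levels
                        * np.exp(rng.normal(0.0, params.sigma_tech, bg_levels.size))
                        * run_eff
                        * lab_eff
                    )
                    std_col += [BACKGROUND] * params.n_background_features
                    idx_col += list(range(1, params.n_background_features + 1))
                    raw.append(bg_vals)
                values = np.concatenate(raw)
                frames.append(
                    pd.DataFrame(
                        {
                            "feature_id": [
                                f"{s}_p{i}" for s, i in zip(std_col, idx_col)
                            ],
                            "standard_id": std_col,
                            "replicate_probe_index": idx_col,
                            "blank": [s == BLANK for s in std_col],
                            "array_id": array_id,
                            "sample": sample,
                            "run": run,
                            "labelling_id": labelling_id,
                            "raw_intensity": values,
                        }
                    )
                )
    table = pd.concat(frames, ignore_index=True)
    rows_per_array = n_probe_rows + params.n_blank_features + params.n_background_features
    assert len(table) % rows_per_array == 0
    return TruthedDataset(design=design, params=params, intensities=table, gains=gains)


def simulate_qpcr(
    design: PanelDesign,
    params: QpcrSimParams | None = None,
    n_runs: int = 3,
) -> TruthedDataset:
    """Generate a long-format Ct table with explicit UNDETERMINED states.

    Each (assay = standard, sample, run) gets ``n_replicates`` reactions.
    Returns a :class:`TruthedDataset` whose ``cts`` frame has columns
    ``assay_id, sample, run, replicate, ct, determined`` (``ct`` is NaN when
    not determined; files serialise the state as the token UNDETERMINED).
    """
    if params is None:
        params = QpcrSimParams()
    if n_runs < 1:
        raise SimulationError("n_runs must be >= 1")
    eff = params.efficiencies_for(design.standard_ids)
    rng = np.random.default_rng(derive_seed(params.seed, "qpcr-noise"))

    rows: list[tuple] = []
    for run in range(1, n_runs + 1):
        run_shift = rng.normal(0.0, params.run_shift_sd)
        for sample in design.samples:
            for aid in design.standard_ids:
                c = design.level_of(aid, sample)
                lam = c * params.reaction_input_ng * params.rt_yield
                for rep in range(1, params.n_replicates + 1):
                    m = float(rng.poisson(lam)) if params.poisson else lam
                    if m <= 0.0:
                        rows.append((aid, sample, run, rep, np.nan, False))
                        continue
                    ct = (
                        params.ct_single_molecule
                        - math.log(m) / math.log1p(eff[aid])
                        + run_shift
                        + (rng.normal(0.0, params.sigma_ct) if params.sigma_ct > 0 else 0.0)
                    )
                    if ct > params.max_cycles or ct <= 0:
                        rows.append((aid, sample, run, rep, np.nan, False))
                    else:
                        rows.append((aid, sample, run, rep, ct, True))
    cts = pd.DataFrame(
        rows, columns=["assay_id", "sample", "run", "replicate", "ct", "determined"]
    )
    return TruthedDataset(design=design, params=params, cts=cts)


def simulate_panel_pair_microarray(
    pair: PanelPair,
    params: ArraySimParams | None = None,
    n_runs: int = 3,
    arrays_per_panel_per_run: int = 2,
) -> TruthedDataset:
    """Simulate both condition panels on shared probe gains.

    Panels A and B are hybridised side by side within each run with matched
    labelling indices (the default pairing used for fold-change estimation:
    ``arrays_per_panel_per_run`` pairs per run, 6 comparisons for the
    canonical 3-run, duplicate-labelling layout).
    """
    merged = PanelDesign(
        standards=list(pair.design_A.standards),
        samples=["A", "B"],
        copies=pd.concat(
            [
                pair.design_A.copies.set_axis(["A"], axis=1),
                pair.design_B.copies.set_axis(["B"], axis=1),
            ],
            axis=1,
        ),
    )
    ds = simulate_microarray(
        merged, params, n_runs=n_runs, arrays_per_sample_per_run=arrays_per_panel_per_run
    )
    ds.expected_fc = dict(pair.expected_fc)
    return ds


def simulate_panel_pair_qpcr(
    pair: PanelPair,
    params: QpcrSimParams | None = None,
    n_runs: int = 3,
) -> TruthedDataset:
    """Simulate both condition panels in the same qPCR runs (plates)."""
    merged = PanelDesign(
        standards=list(pair.design_A.standards),
        samples=["A", "B"],
        copies=pd.concat(
            [
                pair.design_A.copies.set_axis(["A"], axis=1),
                pair.design_B.copies.set_axis(["B"], axis=1),
            ],
            axis=1,
        ),
    )
    ds = simulate_qpcr(merged, params, n_runs=n_runs)
    ds.expected_fc = dict(pair.expected_fc)
    return ds


def simulate_dilution_qpcr(
    assay_id: str,
    relative_inputs: list[float],
    params: QpcrSimParams | None = None,
    top_copies: float = 1e6,
) -> pd.DataFrame:
    """Serial-dilution Ct data for PCR-efficiency estimation.

    Emulates a dilution series of pure cDNA: no RT step and (by default) no
    Poisson sampling, so each point's expected molecule count is
    ``top_copies * relative_input``.  Returns a frame with columns
    ``assay_id, rel_input, replicate, ct, determined``.
    """
    if params is None:
        params = QpcrSimParams(poisson=False, rt_yield=1.0, run_shift_sd=0.0)
    eff = params.efficiencies_for([assay_id])[assay_id]
    rng = np.random.default_rng(derive_seed(params.seed, f"dilution-{assay_id}"))
    rows = []
    for rel in relative_inputs:
        if rel <= 0:
            raise SimulationError("relative inputs must be > 0")
        m = top_copies * rel
        m_draws = (
            rng.poisson(m, params.n_replicates).astype(float)
            if params.poisson
            else np.full(params.n_replicates, m)
        )
        for rep, mi in enumerate(m_draws, start=1):
            if mi <= 0:
                rows.append((assay_id, rel, rep, np.nan, False))
                continue
            ct = params.ct_single_molecule - math.log(mi) / math.log1p(eff)
            if params.sigma_ct > 0:
                ct += rng.normal(0.0, params.sigma_ct)
            if ct > params.max_cycles or ct <= 0:
                rows.append((assay_id, rel, rep, np.nan, False))
            else:
                rows.append((assay_id, rel, rep, ct, True))
    return pd.DataFrame(
        rows, columns=["assay_id", "rel_input", "replicate", "ct", "determined"]
    )
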