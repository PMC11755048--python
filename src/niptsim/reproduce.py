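"""End-to-end reproduction of the pipeline's headline quantities.

Each function runs the relevant stage from scratch — simulating inputs,
executing the method, measuring the result — and returns plain numbers.
``run_all`` bundles them for the ``niptsim reproduce`` CLI command.

All randomness descends from one seed through ``numpy.random.SeedSequence``
spawning, so results are reproducible and stages are independently seeded.
"""

from __future__ import annotations

import numpy as np

from .caller import build_reference
from .cohort import weight_at_ff, weight_ff_regression
from .ff import sequencing_depth
from .fragments import size_histogram, zone_area_ratio
from .io import load_table2
from .mixture import simulate_detection_rate
from .synthetic import (
    CohortParams,
    FFLaw,
    FFLawStratum,
    FragmentLengthParams,
    SequencingParams,
    TruncNormal,
    generate_cohort,
    generate_reference_cohort,
    simulate_fragment_lengths,
)

__all__ = [
    "detection_rate_in_ff_band",
    "fragment_mode_bp",
    "crossing_weight_recovery",
    "table2_summary",
    "run_all",
]

PANEL_SIZE = 412


def _spawn(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def detection_rate_in_ff_band(
    ff_lo: float,
    ff_hi: float,
    n_samples: int,
    seed: int,
    panel_size: int = PANEL_SIZE,
    seq: SequencingParams | None = None,
) -> float:
    """Percent of simulated T21 male-fetus samples called at chr21 z >= 3.

    Builds a fresh euploid reference panel of ``panel_size`` simulated
    samples, then scores ``n_samples`` trisomic profiles with FF uniform in
    [ff_lo, ff_hi] (a point FF when the band is degenerate).
    """
    seq = seq or SequencingParams()
    ss_panel, ss_ff, ss_power = _spawn(seed, 3)
    panel_profiles = generate_reference_cohort(
        panel_size, seq, np.random.default_rng(ss_panel)
    )
    panel = build_reference(panel_profiles)
    rng = np.random.default_rng(ss_ff)
    ffs = rng.uniform(ff_lo, ff_hi, size=n_samples) if ff_hi > ff_lo else np.full(n_samples, ff_lo)
    return simulate_detection_rate(ffs, panel, seq, np.random.default_rng(ss_power))


def fragment_mode_bp(ff: float, n: int, seed: int) -> float:
    """Modal fragment length (1 bp bins) of ``n`` draws at fetal fraction ``ff``."""
    sample = simulate_fragment_lengths(FragmentLengthParams(), ff=ff, n=n, seed=seed)
    return size_histogram(sample, bin_bp=1).mode_bp


def crossing_weight_recovery(
    seed: int,
    n_seeds: int = 20,
    n_samples: int = 2000,
    true_crossing_kg: float = 96.0,
    slope_pct_per_kg: float = -0.12,
    residual_sd_pct: float = 3.0,
    target_ff: float = 0.05,
) -> float:
    """Median recovered 5%-FF crossing weight over ``n_seeds`` synthetic
    early-gestation cohorts.

    Each cohort: n = 2000, weight ~ truncNormal(56, 8) on [40, 110] kg, FF(%)
    = a + b*weight + N(0, 3) with b = -0.12 and a set so the generating line
    crosses ``target_ff`` at ``true_crossing_kg``; OLS fit then inverse
    prediction.
    """
    import warnings

    intercept = target_ff * 100.0 - slope_pct_per_kg * true_crossing_kg
    law = FFLaw(
        strata=(FFLawStratum(12.0, 20.0, intercept, slope_pct_per_kg),),
        residual_sd_pct=residual_sd_pct,
    )
    estimates = []
    for child in _spawn(seed, n_seeds):
        params = CohortParams(
            n_samples=n_samples,
            seed=int(child.generate_state(1)[0] % 2**31),
            ff_law=law,
            weight_law=TruncNormal(56.0, 8.0, 40.0, 110.0),
            ga_law=TruncNormal(16.0, 2.0, 12.0, 19.99),
        )
        records = generate_cohort(params)
        fit = weight_ff_regression(records, stratum=(12.0, 20.0))
        with warnings.catch_warnings():
            # the crossing typically lies above the heaviest observed weight;
            # the extrapolation is the point of the exercise
            warnings.filterwarnings("ignore", message=".*outside the observed range.*")
            estimates.append(weight_at_ff(fit, target_ff=target_ff))
    return float(np.median(estimates))


def table2_summary() -> dict[str, float]:
    """Recompute headline statistics of the packaged T21 case table."""
    cases = load_table2()
    tp = [c for c in cases if c.status == "true_positive"]
    return {
        "min_true_positive_ff_pct": min(c.ff_pct for c in tp),
        "n_high_risk_calls": sum(c.z_chr21 >= 3.0 for c in cases),
        "n_low_risk_calls": sum(c.z_chr21 < 3.0 for c in cases),
    }


def run_all(seed: int) -> dict[str, dict[str, float]]:
    """Recompute the pipeline's main quantities from scratch.

    Returns a mapping of descriptive names to {"value", "n"} entries, on the
    reporting scales (percent, bp, kg, fold coverage).
    """
    ss = np.random.SeedSequence(seed)
    s_det45, s_det10, s_fetal, s_maternal, s_cross = [
        int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(5)
    ]
    t2 = table2_summary()
    return {
        "sequencing_depth_fold": {
            "value": sequencing_depth(1_500_000, 45, 6, 3_000_000_000),
            "n": 1_500_000,
        },
        "min_true_positive_ff_pct": {"value": t2["min_true_positive_ff_pct"], "n": 17},
        "detection_rate_ff_4_5_pct": {
            "value": detection_rate_in_ff_band(0.04, 0.05, 10_000, s_det45),
            "n": 10_000,
        },
        "detection_rate_ff_10_pct": {
            "value": detection_rate_in_ff_band(0.10, 0.10, 100, s_det10),
            "n": 100,
        },
        "fetal_fragment_mode_bp": {
            "value": fragment_mode_bp(1.0, 100_000, s_fetal),
            "n": 100_000,
        },
        "maternal_fragment_mode_bp": {
            "value": fragment_mode_bp(0.0, 100_000, s_maternal),
            "n": 100_000,
        },
        "low_ff_share_pct": {"value": 100.0 * 214 / 4827, "n": 4827},
        "crossing_weight_12_19wk_kg": {
            "value": crossing_weight_recovery(s_cross),
            "n": 2000,
        },
    }
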