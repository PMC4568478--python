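"""Reproducible validation experiments for the perfusion pipeline.

Each function builds its own synthetic inputs, runs the package's public
surface and returns measured quantities; nothing here asserts.  The
protocols (sampling steps, windows, truncations, replicate counts) are the
package's validation operating points and are documented in the methods
note; the parameter-recovery and delay experiments run at fine temporal
sampling (dt = 0.25 s) so that deconvolution fidelity is isolated from the
coarse-sampling discretization factor present at a clinical 1.5 s frame
interval (which cancels in the relative statistics the pipeline reports).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as gstats
from .aif import select_aif_voxels
from .concentration import estimate_baseline, signal_to_concentration
from .deconv import (
    build_convolution_matrix,
    compute_maps,
    perfusion_parameters,
    svd_deconvolve,
)
from .synthetic import (
    CohortSpec,
    PhantomSpec,
    TerritoryTruth,
    build_phantom_atlas,
    default_territory_truths,
    gamma_variate_aif,
    simulate_cohort,
    simulate_phantom_session,
    simulate_tissue_curve,
)
from .territories import TERRITORIES, percent_increase, regional_means, relative_parameters

CBF_GRID = (20.0, 40.0, 60.0, 80.0)
MTT_GRID = (3.0, 4.5, 6.0, 12.0)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic 31-bit child seeds."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# discrete convolution oracle


def convolution_oracle_error(seed: int, n_instances: int = 100) -> float:
    """Worst relative error of the simple-mode matrix against brute force.

    For random AIFs and residue curves, applying the lower-triangular
    operator must equal the direct discrete convolution sum
    ``C[i] = dt * sum_{j<=i} AIF[i-j] x[j]``.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(5, 30))
        dt = float(rng.uniform(0.1, 2.0))
        aifc = rng.uniform(0, 1, n)
        x = rng.normal(0, 1, n)
        system = build_convolution_matrix(aifc, dt, mode="simple", truncation=0.2)
        direct = np.array(
            [dt * sum(aifc[i - j] * x[j] for j in range(i + 1)) for i in range(n)]
        )
        got = system.matrix @ x
        scale = max(np.abs(direct).max(), 1e-300)
        worst = max(worst, float(np.abs(got - direct).max() / scale))
    return worst


# ---------------------------------------------------------------------------
# parameter recovery


def _experiment_aif(dt: float, duration: float, t0: float = 5.0) -> np.ndarray:
    t = np.arange(int(round(duration / dt))) * dt
    return gamma_variate_aif(t, t0=t0, alpha=3.0, beta=1.5, amplitude=1.0)


def noise_free_recovery(
    dt: float = 0.25, duration: float = 150.0, truncation: float = 1e-5
) -> pd.DataFrame:
    """Noise-free circulant recovery over the CBF x MTT grid.

    With no noise, regularization is matched to the noise level: a tiny
    truncation isolates the residual discretization error of the fine
    sampling step.  Returns per-cell relative errors (fractions).
    """
    aifc = _experiment_aif(dt, duration)
    system = build_convolution_matrix(aifc, dt, mode="circulant", truncation=truncation)
    rows = []
    for cbf in CBF_GRID:
        for mtt in MTT_GRID:
            truth = TerritoryTruth(label=1, side="left", cbf=cbf, mtt=mtt)
            curve = simulate_tissue_curve(aifc, truth, dt)
            p = perfusion_parameters(svd_deconvolve(system, curve))
            rows.append(
                {
                    "cbf": cbf,
                    "mtt": mtt,
                    "cbf_rel_err": (p.cbf - cbf) / cbf,
                    "mtt_rel_err": (p.mtt - mtt) / mtt,
                }
            )
    return pd.DataFrame(rows)


def snr_noise_robustness(
    seed: int,
    snr: float = 50.0,
    dt: float = 0.25,
    duration: float = 90.0,
    n_reps: int = 12,
    truncation: float | None = None,
) -> dict:
    """CBF error under signal noise at the default truncation.

    Tissue curves over the CBF x MTT grid are rendered to T2* signal with a
    single relaxivity constant (scaled so a mid-grid curve peaks at unit
    attenuation), Gaussian noise of SD ``s0 / snr`` is added, and the
    curves are converted back and deconvolved.  Returns the median absolute
    relative CBF deviation of the noisy estimate from its noise-free
    counterpart (noise robustness) and, for reference, from the true CBF.
    """
    rng = np.random.default_rng(seed)
    aifc = _experiment_aif(dt, duration)
    n = aifc.size
    system = build_convolution_matrix(aifc, dt, mode="circulant", truncation=truncation)
    ref_truth = TerritoryTruth(label=1, side="left", cbf=40.0, mtt=4.5)
    k_te = 1.0 / simulate_tissue_curve(aifc, ref_truth, dt).max()
    s0 = 100.0
    robustness, vs_truth = [], []
    for cbf in CBF_GRID:
        for mtt in MTT_GRID:
            truth = TerritoryTruth(label=1, side="left", cbf=cbf, mtt=mtt)
            curve = simulate_tissue_curve(aifc, truth, dt)
            clean = perfusion_parameters(svd_deconvolve(system, curve)).cbf
            for _ in range(n_reps):
                signal = s0 * np.exp(-k_te * curve) + rng.normal(0, s0 / snr, n)
                noisy_curve = -np.log(np.maximum(signal, 1e-3 * s0) / s0) / k_te
                p = perfusion_parameters(svd_deconvolve(system, noisy_curve))
                robustness.append(abs(p.cbf - clean) / clean)
                vs_truth.append(abs(p.cbf - cbf) / cbf)
    return {
        "median_abs_rel_cbf_change_vs_noisefree": float(np.median(robustness)),
        "median_abs_rel_cbf_err_vs_truth": float(np.median(vs_truth)),
        "n": len(robustness),
    }


def delay_experiment(
    dt: float = 0.25,
    duration: float = 90.0,
    cbf: float = 60.0,
    mtt: float = 4.0,
    max_delay_frames: int = 3,
) -> dict:
    """CBF estimates versus tissue bolus delay, both operator modes.

    The tissue curve is shifted late by 0..``max_delay_frames`` frames.
    The block-circulant estimate should be insensitive to the shift; the
    simple (causal Toeplitz) estimate degrades as delay grows.
    """
    aifc = _experiment_aif(dt, duration)
    n = aifc.size
    truth = TerritoryTruth(label=1, side="left", cbf=cbf, mtt=mtt)
    base = simulate_tissue_curve(aifc, truth, dt)
    out = {"delays_frames": list(range(max_delay_frames + 1))}
    for mode in ("simple", "circulant"):
        system = build_convolution_matrix(aifc, dt, mode=mode)
        vals = []
        for d in range(max_delay_frames + 1):
            curve = np.concatenate([np.zeros(d), base[: n - d]])
            vals.append(perfusion_parameters(svd_deconvolve(system, curve)).cbf)
        out[mode] = vals
    return out


# ---------------------------------------------------------------------------
# full-pipeline phantom runs


def run_phantom_session(phantom: PhantomSpec, truths=None, surgical_side: str = "left"):
    """Simulate one phantom session and push it through the full pipeline.

    Returns ``(maps, summary, sidecar, atlas)``.
    """
    atlas = build_phantom_atlas(phantom.grid_shape)
    if truths is None:
        truths = default_territory_truths(atlas)
    series, sidecar = simulate_phantom_session(phantom, atlas, truths)
    s0, mask = estimate_baseline(series)
    conc = signal_to_concentration(series, s0, mask, k=phantom.k)
    aif = select_aif_voxels(conc)
    maps = compute_maps(conc, aif)
    means = regional_means(maps, atlas)
    summary = relative_parameters(means, surgical_side)
    return maps, summary, sidecar, atlas


def symmetric_phantom_relative(noise_sd: float = 0.0, seed: int = 0) -> dict:
    """Relative values and central-volume check on a symmetric phantom."""
    phantom = PhantomSpec(noise_sd=noise_sd, seed=seed)
    maps, summary, _, _ = run_phantom_session(phantom)
    sel = maps.mask & (maps.cbf > 0)
    return {
        "max_abs_relative_deviation": float((summary.relative - 1.0).abs().max().max()),
        "central_volume_exact": bool(
            np.array_equal(maps.mtt[sel] * maps.cbf[sel], maps.cbv[sel])
        ),
        "n_voxels": int(sel.sum()),
    }


# ---------------------------------------------------------------------------
# cohort-level statistics experiments


def cohort_effect_replicates(seed: int, n_reps: int = 200) -> dict:
    """Designed-effect recovery over seeded cohort replicates.

    Each replicate draws a 5-CHS / 9-non-CHS cohort (CHS surgical-side
    MCA-terminal intra/pre CBF factor 1.143, non-CHS 1.0, between-subject
    SD 0.07) at the generator's ground-truth layer and tests the
    across-group difference in per-subject relative-CBF %increase in every
    territory.  Returns the detection rate at MCA-terminal (raw p < 0.05)
    and the fraction of replicates in which MCA-terminal is the
    most-significant territory.
    """
    seeds = _child_seeds(seed, n_reps)
    detected = 0
    modal = 0
    for s in seeds:
        table = simulate_cohort(CohortSpec(seed=s)).relative_truth_table()
        pvals = {}
        for territory in TERRITORIES:
            sub = table[table.territory == territory].pivot_table(
                index="subject", columns="session", values="relative_cbf", sort=True
            )
            groups = table[table.territory == territory].drop_duplicates("subject")
            groups = groups.set_index("subject")["group"].loc[sub.index]
            inc = percent_increase(sub["pre"].values, sub["intra"].values)
            res = gstats.independent_ttest(
                inc[groups.values == "CHS"], inc[groups.values == "non-CHS"]
            )
            pvals[territory] = res.pvalue
        if pvals["MCA-terminal"] < 0.05:
            detected += 1
        if min(pvals, key=pvals.get) == "MCA-terminal":
            modal += 1
    return {
        "detection_rate": detected / n_reps,
        "modal_mca_terminal_rate": modal / n_reps,
        "n_reps": n_reps,
    }


def null_calibration(seed: int, n_reps: int = 1000, alpha: float = 0.05) -> pd.DataFrame:
    """Type-I error of every raw test under a null cohort.

    Cohorts are drawn with all group effects zero (between-subject and
    session variability retained).  Rejection rates at ``alpha`` are pooled
    over the five territories — independent draws within each replicate —
    giving ``5 * n_reps`` Bernoulli trials per (test, parameter) cell.
    """
    null_spec = {"CHS": {}, "non-CHS": {}}
    seeds = _child_seeds(seed, n_reps)
    tests = ("paired_all", "paired_chs", "paired_nonchs", "intra_groups", "increase_groups")
    counts = {(t, p): 0 for t in tests for p in ("cbf", "cbv", "mtt")}
    total = 0
    for s in seeds:
        cohort = simulate_cohort(CohortSpec(effect_map=null_spec, seed=s))
        table = cohort.relative_truth_table()
        groups = table.drop_duplicates("subject").set_index("subject")["group"]
        for parameter in ("cbf", "cbv", "mtt"):
            wide = table.pivot_table(
                index="subject", columns=["territory", "session"],
                values=f"relative_{parameter}", sort=True,
            )
            is_chs = (groups.loc[wide.index] == "CHS").values
            for territory in TERRITORIES:
                pre = wide[(territory, "pre")].values
                intra = wide[(territory, "intra")].values
                inc = percent_increase(pre, intra)
                p = {
                    "paired_all": gstats.paired_ttest(pre, intra).pvalue,
                    "paired_chs": gstats.paired_ttest(pre[is_chs], intra[is_chs]).pvalue,
                    "paired_nonchs": gstats.paired_ttest(
                        pre[~is_chs], intra[~is_chs]
                    ).pvalue,
                    "intra_groups": gstats.independent_ttest(
                        intra[is_chs], intra[~is_chs]
                    ).pvalue,
                    "increase_groups": gstats.independent_ttest(
                        inc[is_chs], inc[~is_chs]
                    ).pvalue,
                }
                for test, pv in p.items():
                    counts[(test, parameter)] += pv < alpha
        total += len(TERRITORIES)
    rows = [
        {"test": t, "parameter": par, "rate": counts[(t, par)] / total, "n": total}
        for (t, par) in counts
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg oracle


def bh_step_up_reference(p_values, q: float) -> np.ndarray:
    """Literal step-up definition, independent of the package implementation.

    Checks every rank k from m down to 1 for ``p_(k) <= k q / m`` and
    rejects all hypotheses with p-value at or below the first qualifying
    ``p_(k)``.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    for k in range(m, 0, -1):
        if p[order[k - 1]] <= k * q / m:
            return p <= p[order[k - 1]]
    return np.zeros(m, dtype=bool)


def bh_oracle_mismatches(seed: int, n_vectors: int = 400, max_len: int = 10) -> int:
    """Count disagreements between the BH implementation and the oracle."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_vectors):
        m = int(rng.integers(1, max_len + 1))
        # mix uniform with spiked-small p-values to exercise the boundary
        p = rng.uniform(0, 1, m)
        if rng.random() < 0.5:
            p[: max(1, m // 2)] = rng.uniform(0, 0.1, max(1, m // 2))
        q = float(rng.uniform(0.05, 0.4))
        reject, _ = gstats.benjamini_hochberg(p, q=q)
        if not np.array_equal(reject, bh_step_up_reference(p, q)):
            mismatches += 1
    return mismatches
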