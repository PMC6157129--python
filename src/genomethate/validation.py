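"""Quantitative checks that a simulation run has the properties it claims.

Three families of check:

* parameter recovery — with causal methylation forced to 0 the slope model is
  an ordinary linear model, so the squared correlation between the slope and a
  standardized dosage should recover that SNP's hg2 (and ~0 when methylation
  is forced to 1); the correlation between the baseline-blended slope and the
  standardized baseline should recover the configured constant;
* distributional — pooled moments of the simulated visit-4 betas should match
  the closed-form moments of the clipped Normal implied by the anchors;
* algebraic — reconstructing the slope from the emitted TG values must return
  the simulated slope to floating-point accuracy.

Standard errors: the cohort is fixed across replicates, so the spread of
per-replicate estimates measures only the noise that is redrawn each
replicate.  Estimates are therefore reported with a combined SE that adds the
finite-cohort sampling variance of a correlation, (1 - rho^2)^2 / (n - 1);
without it any fixed finite-cohort deviation would fail an SE-based check as
the replicate count grows.  Pass thresholds are 3 combined SEs by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .baseline import ObservedBaseline
from .cohort import CohortData
from .pipeline import ReplicateOutput, prepare_run, simulate_replicate
from .spec import ModelSpec

__all__ = [
    "CheckResult",
    "ValidationReport",
    "clipped_normal_moments",
    "replicate_correlations",
    "estimate_locus_h2",
    "check_baseline_corr",
    "roundtrip_check",
    "validate_run",
]


@dataclass
class CheckResult:
    name: str
    value: float
    target: float
    tol: float
    passed: bool
    se: float | None = None
    n: int | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "value": self.value,
            "target": self.target,
            "tol": self.tol,
            "se": self.se,
            "n": self.n,
            "passed": bool(self.passed),
        }


@dataclass
class ValidationReport:
    checks: list[CheckResult] = field(default_factory=list)
    seed: int | None = None
    n_replicates: int | None = None

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "passed": bool(self.passed),
            "checks": [c.to_dict() for c in self.checks],
        }

    def to_text(self) -> str:
        lines = [
            f"validation report (seed={self.seed}, replicates={self.n_replicates})",
            "-" * 72,
        ]
        for c in self.checks:
            se = f" se={c.se:.3g}" if c.se is not None else ""
            lines.append(
                f"[{'PASS' if c.passed else 'FAIL'}] {c.name}: "
                f"value={c.value:.6g} target={c.target:.6g} tol={c.tol:.3g}{se}"
            )
        lines.append("-" * 72)
        lines.append("overall: " + ("PASS" if self.passed else "FAIL"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# clipped-normal oracle


def clipped_normal_moments(
    mu, sigma: float, lo: float = 0.0, hi: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of clip(X, lo, hi) for X ~ N(mu, sigma^2), element-wise.

    Censoring (not truncation-by-rejection): boundary mass stays at the
    boundary.  Closed form from standard-normal partial moments.
    """
    mu = np.asarray(mu, float)
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    mid = Fb - Fa
    # partial moments of Z on [a, b]
    ez = fa - fb
    ez2 = mid + a * fa - b * fb
    m1 = lo * Fa + hi * (1 - Fb) + mu * mid + sigma * ez
    m2 = (
        lo**2 * Fa
        + hi**2 * (1 - Fb)
        + mu**2 * mid
        + 2 * mu * sigma * ez
        + sigma**2 * ez2
    )
    var = np.maximum(m2 - m1**2, 0.0)
    return m1, np.sqrt(var)


# ---------------------------------------------------------------------------
# recovery estimators


def replicate_correlations(values: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Sample correlation of each row of ``values`` (R x n) with ``x`` (n)."""
    values = np.asarray(values, float)
    x = np.asarray(x, float)
    vc = values - values.mean(axis=1, keepdims=True)
    xc = x - x.mean()
    num = vc @ xc
    den = np.sqrt((vc**2).sum(axis=1) * (xc**2).sum())
    return num / den


def _corr_se(r: np.ndarray, rbar: float, n: int) -> float:
    """Combined SE of a mean-over-replicates correlation estimate.

    Replicate spread covers the redrawn noise; the (1-rho^2)^2/(n-1) term
    covers the cohort-level sampling that is frozen across replicates.
    """
    var_rep = float(np.var(r, ddof=1)) / len(r) if len(r) > 1 else 0.0
    var_cohort = (1.0 - rbar**2) ** 2 / (n - 1)
    return float(np.sqrt(var_rep + var_cohort))


def estimate_locus_h2(
    slopes: np.ndarray, ssnp: np.ndarray
) -> tuple[float, float]:
    """Variance explained by one SNP: mean per-replicate correlation, squared.

    Averaging correlations before squaring keeps the O(1/n) chi-square bias of
    squared sample correlations from swamping hg2 values as small as 0.001.
    Returns (estimate, SE); the SE propagates the correlation SE through the
    square (delta method plus the second-order term, which dominates at
    rho ~ 0).
    """
    ssnp = np.asarray(ssnp, float)
    if ssnp.std() == 0:
        raise ValueError("monomorphic SNP: correlation undefined")
    r = replicate_correlations(slopes, ssnp)
    rbar = float(r.mean())
    n = slopes.shape[1]
    se_rho = _corr_se(r, rbar, n)
    se_h2 = float(np.sqrt(4 * rbar**2 * se_rho**2 + 2 * se_rho**4))
    return rbar**2, se_h2


def check_baseline_corr(
    corrz: np.ndarray, preZ: np.ndarray
) -> tuple[float, float]:
    """Mean across replicates of corr(corrz_k, preZ), with combined SE."""
    r = replicate_correlations(corrz, preZ)
    rbar = float(r.mean())
    return rbar, _corr_se(r, rbar, corrz.shape[1])


def roundtrip_check(
    outputs: list[ReplicateOutput], baseline: ObservedBaseline
) -> float | None:
    """Max |slope reconstructed from emitted TG - simulated slope|.

    Needs diagnostics on the outputs.  Returns None when no subject has
    complete data (check not applicable).
    """
    table = baseline.table
    pre = table["O_preRx_TG"].to_numpy()
    days = table["O_daysRx"].to_numpy()
    worst = None
    for out in outputs:
        if out.diagnostics is None:
            raise ValueError("roundtrip_check needs outputs with diagnostics")
        sim_tg3 = out.tg["SIMTG3"].to_numpy(float)
        sim_tg4 = out.tg["SIMTG4"].to_numpy(float)
        sim_slope = out.diagnostics["sim_slope_jk"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            recon = ((np.log(sim_tg3) + np.log(sim_tg4)) / 2.0 - pre) / days
        err = np.abs(recon - sim_slope)
        ok = np.isfinite(err)
        if ok.any():
            m = float(err[ok].max())
            worst = m if worst is None else max(worst, m)
    return worst


# ---------------------------------------------------------------------------
# end-to-end validation


def _collect(run, reps, force_meth, diagnostics=False, keep_raw=False):
    outs = [
        simulate_replicate(run, k, force_meth=force_meth,
                           diagnostics=diagnostics, keep_raw=keep_raw)
        for k in reps
    ]
    return outs


def validate_run(
    cohort: CohortData,
    spec: ModelSpec,
    n_replicates: int | None = None,
    n_sigma: float = 3.0,
) -> ValidationReport:
    """Run the simulator on a cohort and check every recoverable property.

    Heritability and correlation checks intervene on the causal methylation
    (forcing 0 or 1) so the targets are the configured constants; the
    methylation-moment and round-trip checks run the unmodified model.
    """
    R = n_replicates or spec.n_replicates
    run = prepare_run(cohort, spec)
    reps = range(1, R + 1)
    report = ValidationReport(seed=spec.base_seed, n_replicates=R)
    n = len(cohort.subjects)

    # --- forced-0 run: full genetic effects ------------------------------
    outs0 = _collect(run, reps, force_meth=0.0, diagnostics=True)
    slopes0 = np.vstack([o.diagnostics["slope_jk"].to_numpy() for o in outs0])
    corrz0 = np.vstack([o.diagnostics["corrz_jk"].to_numpy() for o in outs0])

    for snp in spec.major_snps:
        h2, se = estimate_locus_h2(slopes0, run.ssnp[snp.marker_name].to_numpy())
        tol = n_sigma * se
        report.checks.append(
            CheckResult(
                f"h2[{snp.marker_name}] (meth=0)", h2, snp.hg2, tol,
                abs(h2 - snp.hg2) <= tol, se=se, n=n,
            )
        )
    bg = spec.background_snps[0]
    h2, se = estimate_locus_h2(slopes0, run.ssnp[bg.marker_name].to_numpy())
    tol = n_sigma * se
    report.checks.append(
        CheckResult(
            f"h2[{bg.marker_name}] (background, meth=0)", h2, bg.hg2, tol,
            abs(h2 - bg.hg2) <= tol, se=se, n=n,
        )
    )

    est, se = check_baseline_corr(corrz0, run.baseline.table["O_preZ"].to_numpy())
    tol = n_sigma * se
    report.checks.append(
        CheckResult(
            "corr(corrz, O_preZ) (meth=0)", est, spec.corr_baseline, tol,
            abs(est - spec.corr_baseline) <= tol, se=se, n=n,
        )
    )

    var = float(slopes0.var(ddof=1))
    # replicate spread covers redrawn noise; the 2*var^2/(n-1) term is an upper
    # bound on the frozen-cohort genetic variance component
    v_k = slopes0.var(axis=1, ddof=1)
    se_var = float(np.sqrt(np.var(v_k, ddof=1) / len(v_k) + 2.0 * var**2 / (n - 1)))
    tol = n_sigma * se_var
    report.checks.append(
        CheckResult(
            "var(slope) (meth=0)", var, 1.0, tol, abs(var - 1.0) <= tol,
            se=se_var, n=slopes0.size,
        )
    )

    # --- forced-1 run: full silencing ------------------------------------
    outs1 = _collect(run, reps, force_meth=1.0, diagnostics=True)
    slopes1 = np.vstack([o.diagnostics["slope_jk"].to_numpy() for o in outs1])
    for snp in spec.major_snps:
        h2, se = estimate_locus_h2(slopes1, run.ssnp[snp.marker_name].to_numpy())
        tol = n_sigma * max(se, 1e-12)
        report.checks.append(
            CheckResult(
                f"h2[{snp.marker_name}] (meth=1)", h2, 0.0, tol, h2 <= tol,
                se=se, n=n,
            )
        )

    # --- unmodified run: moments + algebra --------------------------------
    outs = _collect(run, reps, force_meth=None, diagnostics=True, keep_raw=True)
    from .methylation import anchor_matrix

    anchors = anchor_matrix(cohort.methylation, spec)
    for site in spec.causal_cpgs:
        a = anchors[site.cpg_name].to_numpy()
        m_pred, s_pred = clipped_normal_moments(a, site.sd_response)
        mean_pred = float(m_pred.mean())
        sd_pred = float(np.sqrt((s_pred**2 + m_pred**2).mean() - mean_pred**2))
        vals = np.concatenate([o.methylation.v4_sim[site.cpg_name].to_numpy() for o in outs])
        se_mean = sd_pred / np.sqrt(vals.size)
        tol = n_sigma * se_mean
        report.checks.append(
            CheckResult(
                f"v4 mean[{site.cpg_name}]", float(vals.mean()), mean_pred, tol,
                abs(float(vals.mean()) - mean_pred) <= tol, se=se_mean, n=vals.size,
            )
        )
        se_sd = sd_pred / np.sqrt(2 * vals.size)
        tol = n_sigma * se_sd
        report.checks.append(
            CheckResult(
                f"v4 sd[{site.cpg_name}]", float(vals.std(ddof=1)), sd_pred, tol,
                abs(float(vals.std(ddof=1)) - sd_pred) <= tol, se=se_sd, n=vals.size,
            )
        )

    err = roundtrip_check(outs, run.baseline)
    if err is not None:
        report.checks.append(
            CheckResult("TG round-trip max error", err, 0.0, 1e-10, err <= 1e-10)
        )
    return report
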