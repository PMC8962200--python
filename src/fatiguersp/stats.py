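"""Within-subject inference over ERSP maps, spectra and band scalars.

Three layers, matching how graded-fatigue contrasts are usually reported:

* a surrogate permutation test over time-frequency maps or time-averaged
  spectra, using the one-way repeated-measures ANOVA F statistic at every
  point and a null built by permuting the three condition labels within
  each subject (paired design, sampling without replacement);
* Benjamini-Hochberg FDR control over the per-point permutation p-values;
* a parametric one-way repeated-measures ANOVA on band-averaged scalars,
  with Bonferroni-corrected paired-t post-hoc comparisons run only when
  the omnibus test is significant.

The permutation and parametric paths share the same closed-form F
(sum-of-squares decomposition, vectorised across points and permutations);
p-values use the add-one rule (1 + #{F_perm >= F_obs}) / (1 + n_perm) so
they can never be zero, and ties count against rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import CONDITIONS, ConfigurationError, StructureError

#: Condition pairs reported by the post-hoc analysis.
PAIRS = (("MinFatg", "ModFatg"), ("MinFatg", "SevFatg"), ("ModFatg", "SevFatg"))


@dataclass
class PermutationResult:
    """Per-point permutation F test with BH-FDR mask at q."""

    observed_stat: np.ndarray
    p_map: np.ndarray
    fdr_mask: np.ndarray
    n_perm: int
    seed: int
    q: float = 0.05


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA across the three fatigue conditions.

    ``posthoc`` maps condition pairs to Bonferroni-adjusted paired-t
    p-values; it is empty when the omnibus p is not below ``alpha``
    (reported as "--" in summary tables).
    """

    F: float
    df: tuple[int, int]
    p: float
    N: int
    k: int
    posthoc: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha: float = 0.05


def _as_cube(data) -> np.ndarray:
    """Coerce dict/sequence of per-condition (N x points) arrays to N x k x P."""
    if isinstance(data, dict):
        mats = [np.asarray(data[c], dtype=float) for c in CONDITIONS]
    else:
        mats = [np.asarray(m, dtype=float) for m in data]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise StructureError(f"condition matrices have mismatched shapes {shapes}")
    cube = np.stack(mats, axis=1)  # N x k x ...
    if cube.shape[0] < 2:
        raise StructureError("need N >= 2 subjects/components")
    return cube.reshape(cube.shape[0], cube.shape[1], -1)


def rm_f_statistic(cube: np.ndarray) -> np.ndarray:
    """Repeated-measures F per point for an N x k x P (or N x k) array.

    F = MS_condition / MS_(condition x subject); both zero (all cells
    identical along conditions and subjects) yields F = 0 by convention.
    """
    if cube.ndim == 2:
        cube = cube[..., None]
    N, k, P = cube.shape
    grand = cube.mean(axis=(0, 1))
    cond_mean = cube.mean(axis=0)        # k x P
    subj_mean = cube.mean(axis=1)        # N x P
    ss_cond = N * ((cond_mean - grand) ** 2).sum(axis=0)
    resid = cube - cond_mean[None] - subj_mean[:, None] + grand
    ss_err = (resid ** 2).sum(axis=(0, 1))
    ms_cond = ss_cond / (k - 1)
    ms_err = ss_err / ((k - 1) * (N - 1))
    # degenerate detection relative to the data scale, not exact zero
    ss_tot = ((cube - grand) ** 2).sum(axis=(0, 1))
    tol = 1e-12 * np.maximum(ss_tot, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_cond / ms_err
    F = np.where(ms_err <= tol,
                 np.where(ms_cond <= tol, 0.0, np.inf), F)
    return F


def permutation_test(data, n_perm: int = 2000, seed: int = 0,
                     q: float = 0.05, chunk: int = 200) -> PermutationResult:
    """Paired surrogate permutation test across the three fatigue conditions.

    ``data``: dict or sequence of three N x points arrays (subjects or IC
    components x TF grid points or frequencies).  The null permutes the
    condition labels independently within each row; the observed statistic
    is the repeated-measures F at each point.
    """
    cube = _as_cube(data)
    N, k, P = cube.shape
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    f_obs = rm_f_statistic(cube)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(P, dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # per (perm, subject) independent permutation of the k labels
        order = np.argsort(rng.random((m, N, k)), axis=2)
        permuted = np.take_along_axis(
            cube[None].repeat(m, axis=0), order[..., None], axis=2
        )
        f_perm = rm_f_statistic(
            permuted.transpose(1, 2, 0, 3).reshape(N, k, m * P)
        ).reshape(m, P)
        exceed += (f_perm >= f_obs[None]).sum(axis=0)
        done += m
    p_map = (1.0 + exceed) / (1.0 + n_perm)
    mask = fdr_correct(p_map, q)
    return PermutationResult(
        observed_stat=f_obs, p_map=p_map, fdr_mask=mask,
        n_perm=n_perm, seed=seed, q=q,
    )


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise StructureError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise StructureError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject.reshape(np.shape(p_values))


def greenhouse_geisser_epsilon(table: np.ndarray) -> float:
    """Sphericity correction factor from the double-centred covariance."""
    table = np.asarray(table, dtype=float)
    k = table.shape[1]
    cov = np.cov(table, rowvar=False)
    centred = (cov - cov.mean(axis=0, keepdims=True)
               - cov.mean(axis=1, keepdims=True) + cov.mean())
    num = np.trace(centred) ** 2
    den = (k - 1) * np.sum(centred ** 2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(table: np.ndarray, alpha: float = 0.05,
             run_posthoc: bool = True,
             greenhouse_geisser: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA on an N-subjects x 3-conditions table.

    F = MS_condition / MS_(condition x subject), df = (k-1, (k-1)(N-1)).
    Bonferroni paired-t post-hoc comparisons are attached only when the
    omnibus p is below ``alpha``.  ``greenhouse_geisser=True`` rescales the
    degrees of freedom by the sphericity epsilon (off by default: the
    plain RM-ANOVA is the reported statistic).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != len(CONDITIONS):
        raise StructureError("table must be N x 3 (MinFatg, ModFatg, SevFatg)")
    if np.any(~np.isfinite(table)):
        raise StructureError("missing or non-finite cells (no imputation)")
    N, k = table.shape
    if N < 2:
        raise StructureError("need N >= 2")
    F = float(rm_f_statistic(table[:, :, None])[0])
    df = (k - 1, (k - 1) * (N - 1))
    eps = greenhouse_geisser_epsilon(table) if greenhouse_geisser else 1.0
    p = 1.0 if F == 0 else float(sps.f.sf(F, eps * df[0], eps * df[1]))
    res = AnovaResult(F=F, df=df, p=p, N=N, k=k, alpha=alpha)
    if run_posthoc and p < alpha:
        res.posthoc = bonferroni_posthoc(table, force=True)
    return res


def bonferroni_posthoc(table: np.ndarray,
                       force: bool = False) -> dict[tuple[str, str], float]:
    """Bonferroni-adjusted paired two-sided t-tests per condition pair.

    Normally gated on a significant omnibus ANOVA (call through
    :func:`rm_anova`); ``force=True`` runs regardless.  Degenerate
    zero-variance paired differences give p = 0 when the mean difference is
    non-zero and p = 1 otherwise.
    """
    table = np.asarray(table, dtype=float)
    if not force:
        gate = rm_anova(table, run_posthoc=False)
        if gate.p >= gate.alpha:
            return {}
    cols = {c: table[:, i] for i, c in enumerate(CONDITIONS)}
    out = {}
    for a, b in PAIRS:
        diff = cols[a] - cols[b]
        if np.allclose(diff.std(ddof=1), 0.0):
            raw = 0.0 if abs(diff.mean()) > 0 else 1.0
        else:
            raw = float(sps.ttest_rel(cols[a], cols[b]).pvalue)
        out[(a, b)] = min(1.0, 3.0 * raw)
    return out
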