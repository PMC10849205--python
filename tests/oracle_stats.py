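"""Independent permutation/enumeration oracles for the inferential statistics.

These deliberately avoid scipy/statsmodels test functions: the paired t-test
is checked against exact sign-flip enumeration, the repeated-measures ANOVA
against a within-subject label-permutation null of the F statistic, and the
Tukey-adjusted pairwise p against a max-|q| permutation distribution.
"""

from __future__ import annotations

import numpy as np


def exact_signflip_p(a, b) -> float:
    """Exact two-sided sign-flip p for paired data (enumerates all 2^n flips).

    The p-value is the fraction of sign assignments whose |mean difference|
    is at least the observed one.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    n = len(d)
    assert n <= 16, "enumeration oracle is for small n"
    signs = np.array(
        [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)]
    )
    means = (signs * d).mean(axis=1)
    obs = abs(d.mean())
    return float(np.mean(np.abs(means) >= obs - 1e-12))


def _rm_f_stat(mat: np.ndarray) -> np.ndarray:
    """Repeated-measures one-way F for (..., n_subjects, k_levels) arrays."""
    grand = mat.mean(axis=(-1, -2), keepdims=True)
    level_means = mat.mean(axis=-2, keepdims=True)
    subj_means = mat.mean(axis=-1, keepdims=True)
    n, k = mat.shape[-2], mat.shape[-1]
    ss_treat = n * ((level_means - grand) ** 2).sum(axis=(-1, -2))
    resid = mat - level_means - subj_means + grand
    ss_err = (resid**2).sum(axis=(-1, -2))
    df_t = k - 1
    df_e = (n - 1) * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ss_treat / df_t) / (ss_err / df_e)


def rm_anova_permutation_p(mat: np.ndarray, reps: int = 100_000, seed: int = 0) -> float:
    """Within-subject permutation p for the RM one-way ANOVA F statistic.

    ``mat`` is (n_subjects, k_levels); level labels are permuted independently
    within every subject.
    """
    rng = np.random.default_rng(seed)
    n, k = mat.shape
    obs = _rm_f_stat(mat)
    order = np.argsort(rng.random((reps, n, k)), axis=-1)
    perm = np.take_along_axis(np.broadcast_to(mat, (reps, n, k)), order, axis=-1)
    null = _rm_f_stat(perm)
    return float((np.sum(null >= obs - 1e-12) + 1) / (reps + 1))


def oneway_anova_permutation_p(groups, reps: int = 100_000, seed: int = 0) -> float:
    """Label-permutation p for the ordinary one-way ANOVA F statistic."""
    from scipy.stats import f_oneway

    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    obs = f_oneway(*groups).statistic

    def split(x):
        out, i = [], 0
        for s in sizes:
            out.append(x[i : i + s])
            i += s
        return out

    count = 0
    for _ in range(reps):
        perm = pooled[rng.permutation(len(pooled))]
        if f_oneway(*split(perm)).statistic >= obs - 1e-12:
            count += 1
    return (count + 1) / (reps + 1)


def tukey_maxq_permutation_p(
    mat: np.ndarray, pair: tuple[int, int], reps: int = 20_000, seed: int = 0
) -> float:
    """Max-|q| permutation estimate of the Tukey-adjusted p for one level pair.

    The studentized range statistic of the pair is compared against the
    permutation distribution of the maximum pairwise |q| (within-subject
    label permutations), which controls the family-wise error the same way
    Tukey's HSD does.
    """
    rng = np.random.default_rng(seed)
    n, k = mat.shape

    def q_stats(m):
        level_means = m.mean(axis=-2)
        grand = m.mean(axis=(-1, -2), keepdims=True)
        resid = (
            m
            - m.mean(axis=-2, keepdims=True)
            - m.mean(axis=-1, keepdims=True)
            + grand
        )
        ms_err = (resid**2).sum(axis=(-1, -2)) / ((n - 1) * (k - 1))
        se = np.sqrt(ms_err / n)
        return level_means, se

    means, se = q_stats(mat)
    i, j = pair
    obs = abs(means[i] - means[j]) / se

    order = np.argsort(rng.random((reps, n, k)), axis=-1)
    perm = np.take_along_axis(np.broadcast_to(mat, (reps, n, k)), order, axis=-1)
    pmeans, pse = q_stats(perm)
    diffs = np.abs(pmeans[..., :, None] - pmeans[..., None, :])
    maxq = diffs.max(axis=(-1, -2)) / pse
    return float((np.sum(maxq >= obs - 1e-12) + 1) / (reps + 1))
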