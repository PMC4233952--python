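import numpy as np
import pandas as pd
import pytest

from mrnadecay import ExpressionMatrix, SampleSheet, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noise-free cohort: 400 genes, 2 donors per group."""
    cfg = SimConfig(
        n_genes=400,
        n_donors_per_group={"normal": 2, "intact_OA": 2, "fibrillated_OA": 2},
        frac_short_lived=0.2,
        short_halflife_range_h=(1.0, 4.0),
        frac_destabilized_in_OA=0.1,
        destabilization_fold=3.0,
        noise_sd_log=0.0,
        frac_undetected=0.2,
        seed=11,
    )
    return (cfg, *simulate_cohort(cfg))


@pytest.fixture()
def tiny_matrix():
    """3 probes x 2 samples with detection p-values."""
    ids = pd.Index(["p1", "p2", "p3"], name="probe_id")
    cols = ["s1", "s2"]
    return ExpressionMatrix(
        pd.DataFrame([[10.0, 20.0], [5.0, 2.0], [100.0, 90.0]], index=ids, columns=cols),
        pd.DataFrame([[0.01, 0.02], [0.5, 0.9], [0.001, 0.001]], index=ids, columns=cols),
    )


@pytest.fixture()
def four_donor_sheet():
    rows = []
    for donor, group in [
        ("n1", "normal"),
        ("n2", "normal"),
        ("o1", "intact_OA"),
        ("o2", "fibrillated_OA"),
    ]:
        for t in (0.0, 1.0, 3.0, 5.0):
            rows.append(
                {"sample_id": f"{donor}_t{t:g}", "donor_id": donor, "group": group, "time_h": t}
            )
    return SampleSheet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Independent oracles, deliberately written as plain loops over definitions.


def ols_slope_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    num = sum((xi - xbar) * (yi - ybar) for xi, yi in zip(x, y))
    den = sum((xi - xbar) ** 2 for xi in x)
    return num / den


def quantile_norm_oracle(columns):
    """Brute-force rank-mean quantile normalization with tie averaging."""
    cols = [np.asarray(c, float) for c in columns]
    ref = np.mean([np.sort(c) for c in cols], axis=0)
    out = []
    for c in cols:
        order = np.argsort(c, kind="mergesort")
        sorted_c = c[order]
        res = np.empty_like(c)
        for v in np.unique(c):
            span = np.nonzero(sorted_c == v)[0]
            res[c == v] = ref[span].mean()
        out.append(res)
    return out


def anova_oracle(groups):
    """Textbook sums-of-squares one-way ANOVA."""
    from scipy import stats

    groups = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    f = (ss_b / df_b) / (ss_w / df_w)
    return f, stats.f.sf(f, df_b, df_w)


def pooled_t_oracle(a, b):
    """Closed-form pooled-variance two-sample t-test."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return t, 2 * stats.t.sf(abs(t), na + nb - 2)


def bh_oracle(pvalues):
    """Brute-force BH: sort, multiply, cumulative minimum from largest, unsort."""
    p = np.asarray(pvalues, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
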