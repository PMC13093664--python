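"""Independent oracles shared by the test suite.

Everything here is deliberately naive -- brute-force enumeration and
closed-form population algebra -- and never calls the code paths it is
used to check.
"""

import numpy as np

#: Var(age) under uniform sampling on [35, 75).
VAR_AGE_UNIFORM = 40.0 ** 2 / 12.0


def hl_two_sample_brute(x, y):
    """Median of the full pairwise difference multiset."""
    diffs = [xi - yj for xi in x for yj in y]
    return float(np.median(diffs))


def hl_one_sample_brute(x):
    """Median of all Walsh averages (x_i + x_j)/2, i <= j."""
    x = list(x)
    walsh = [(x[i] + x[j]) / 2.0 for i in range(len(x)) for j in range(i, len(x))]
    return float(np.median(walsh))


def marker_age_corr(age_slope, pace_loading, noise_sd, pace_sd,
                    var_age=VAR_AGE_UNIFORM):
    """Closed-form population correlation of a generated marker with age."""
    num = age_slope * np.sqrt(var_age)
    den = np.sqrt(age_slope ** 2 * var_age
                  + pace_loading ** 2 * pace_sd ** 2 + noise_sd ** 2)
    return num / den


def population_weights(panel_spec, pace_sd, var_age=VAR_AGE_UNIFORM):
    """Population regression weights of age on the z-scaled panel.

    With marker_i = a_i*A + g_i*P + eps_i and A, P, eps independent,
    Cov(m_i, m_j) = a_i a_j Var(A) + g_i g_j pace_sd^2 (+ noise_i^2 on
    the diagonal) and Cov(m_i, A) = a_i Var(A); the z-scale weights are
    Sigma_z^{-1} Cov(z, A).
    """
    a = np.array([m.age_slope for m in panel_spec])
    g = np.array([m.pace_loading for m in panel_spec])
    noise = np.array([m.noise_sd for m in panel_spec])
    sigma = (np.outer(a, a) * var_age + np.outer(g, g) * pace_sd ** 2
             + np.diag(noise ** 2))
    sd = np.sqrt(np.diag(sigma))
    sigma_z = sigma / np.outer(sd, sd)
    cov_z_age = a * var_age / sd
    return np.linalg.solve(sigma_z, cov_z_age)


def exhaustive_best_subset(panel, age, size):
    """Reference best subset by full enumeration with numpy lstsq."""
    from itertools import combinations

    cols = list(panel.columns)
    y = np.asarray(age, dtype=float)
    best_r2, best_names = -np.inf, None
    tss = np.sum((y - y.mean()) ** 2)
    for combo in combinations(sorted(cols), size):
        X = np.column_stack([np.ones(len(y)), panel[list(combo)].to_numpy()])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        r2 = 1.0 - np.sum(resid ** 2) / tss
        if r2 > best_r2 + 1e-12:
            best_r2, best_names = r2, tuple(sorted(combo))
    return best_names, best_r2
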