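"""Trajectory-comparison metrics.

The agreement between a simulated and a measured 3-D marker trajectory is
scored with the Pitermann–Munhall 3-D correlation coefficient

    rho(v, w) = [ (1/n) sum_i v_i . w_i  -  mu_v . mu_w ] / (sigma_v sigma_w)

where mu is the mean position and sigma the 3-D standard deviation

    sigma_v = sqrt( (1/(n-1)) sum_i ||v_i - mu_v||^2 ).

As printed, the numerator uses 1/n while sigma uses 1/(n-1); the two do
not cancel, so rho(v, v) = (n-1)/n rather than 1.  The formulas are
implemented exactly as printed by default; ``consistent=True`` switches
both to 1/n, which makes rho an exact 3-D generalisation of the Pearson
coefficient with rho(v, v) = 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def corr3d(v: np.ndarray, w: np.ndarray, consistent: bool = False) -> float:
    """3-D correlation coefficient between two (n x 3) trajectories.

    Raises on length mismatch, n < 2, or a constant trajectory (undefined
    correlation).
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape or v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("v and w must both be (n x 3) trajectories")
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    mu_v = v.mean(axis=0)
    mu_w = w.mean(axis=0)
    ddof = 0 if consistent else 1
    var_v = np.sum((v - mu_v) ** 2) / (n - ddof)
    var_w = np.sum((w - mu_w) ** 2) / (n - ddof)
    if var_v == 0.0 or var_w == 0.0:
        raise ValueError("correlation undefined for a constant trajectory")
    num = float(np.mean(np.sum(v * w, axis=1)) - mu_v @ mu_w)
    return num / float(np.sqrt(var_v * var_w))


def summarise(
    report: pd.DataFrame,
    group_by: str | list[str] | None = None,
    value: str = "rho",
) -> pd.DataFrame:
    """Mean, sample standard deviation and median of rho per group.

    ``group_by`` may name one or more report columns (e.g. ``"strategy"``,
    ``"instruction"``, ``"marker"``); ``None`` gives the overall row only.
    Single-observation groups report std 0 with ``std_defined = False``.
    """
    if report.empty:
        raise ValueError("cannot summarise an empty report")
    if value not in report.columns:
        raise KeyError(f"no column {value!r} in report")

    def _stats(x: pd.Series) -> pd.Series:
        n = len(x)
        return pd.Series(
            {
                "n": n,
                "mean": x.mean(),
                "std": x.std(ddof=1) if n > 1 else 0.0,
                "std_defined": n > 1,
                "median": x.median(),
            }
        )

    overall = _stats(report[value]).to_frame().T
    overall.insert(0, "group", "overall")
    if group_by is None:
        return overall.reset_index(drop=True)
    keys = [group_by] if isinstance(group_by, str) else list(group_by)
    for k in keys:
        if k not in report.columns:
            raise KeyError(f"unknown grouping key {k!r}")
    grouped = (
        report.groupby(keys, sort=True)[value].apply(_stats).unstack()
    ).reset_index()
    grouped.insert(0, "group", "+".join(keys))
    return pd.concat([grouped, overall], ignore_index=True)


def boxplot_report(report: pd.DataFrame, path: str) -> None:
    """Write the three standard boxplot groupings to ``path`` (figure).

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groupings = [g for g in ("dataset", "instruction", "marker")
                 if g in report.columns]
    fig, axes = plt.subplots(1, len(groupings),
                             figsize=(5 * len(groupings), 4))
    axes = np.atleast_1d(axes)
    for ax, g in zip(axes, groupings):
        keys = sorted(report[g].unique())
        data = [report.loc[report[g] == k, "rho"].to_numpy() for k in keys]
        ax.boxplot(data, tick_labels=[str(k) for k in keys])
        ax.set_xlabel(g)
        ax.set_ylabel("3-D correlation")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
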