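"""Community-deprivation analysis: KRLS effects of SES on accessibility.

For each travel mode the accessibility score (m2/person) is regressed on the
community SES proportions with KRLS; the average and quantile marginal
effects per covariate form one table block per mode, with significance stars
on the average effect.  A change analysis regresses the between-period
accessibility difference on the SES proportion differences.

Effects are reported in response units (m2/person per unit covariate
proportion); covariates are standardized internally by the KRLS fit and
rescaled back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import krls
from .accessibility import AccessResult

TABLE_MODES = ("walking", "cycling", "public_transport", "integrated")

STAR_LEGEND = "* p < 0.05, ** p < 0.01, *** p < 0.001"


@dataclass
class DeprivationTable:
    """(covariate, mode) rows of avg/P25/P50/P75 marginal effects."""

    rows: pd.DataFrame  # columns: covariate, mode, avg, p25, p50, p75, se, p_value, stars
    modes: tuple[str, ...]
    covariates: tuple[str, ...]
    n_communities: int
    meta: dict = field(default_factory=dict)


def _fit_block(y: np.ndarray, ses: pd.DataFrame, covariates: list[str], mode: str,
               joint: bool) -> list[dict]:
    rows = []
    if np.ptp(y) == 0.0:
        # constant response (e.g. change analysis between identical
        # timepoints): the surface is flat, every marginal effect is zero
        for cov in covariates:
            rows.append(
                {"covariate": cov, "mode": mode, "avg": 0.0, "p25": 0.0, "p50": 0.0,
                 "p75": 0.0, "se": 0.0, "p_value": 1.0, "stars": ""}
            )
        return rows
    if joint:
        try:
            design = krls.standardize(ses[covariates].to_numpy(), y, names=covariates)
        except ValueError as err:
            raise ValueError(f"mode {mode!r}: {err}") from err
        f = krls.fit(design)
        eff = krls.pointwise_derivatives(f, design)
        summ = krls.summarize_effects(eff)
        for _, r in summ.iterrows():
            rows.append({"covariate": r["covariate"], "mode": mode, **r.drop("covariate").to_dict()})
    else:
        for cov in covariates:
            design = krls.standardize(ses[[cov]].to_numpy(), y, names=[cov])
            f = krls.fit(design)
            eff = krls.pointwise_derivatives(f, design)
            r = krls.summarize_effects(eff).iloc[0]
            rows.append({"covariate": cov, "mode": mode, **r.drop("covariate").to_dict()})
    return rows


def cross_sectional_analysis(
    access: AccessResult,
    ses: pd.DataFrame,
    covariates: list[str],
    modes: tuple[str, ...] = TABLE_MODES,
    joint: bool = True,
) -> DeprivationTable:
    """KRLS of accessibility on SES covariates, one block per mode.

    ``ses`` is indexed by community id.  Covariates enter jointly by default
    (``joint=False`` fits them one at a time).
    """
    acc = access.table
    missing_a = sorted(set(acc.index) - set(ses.index))
    missing_s = sorted(set(ses.index) - set(acc.index))
    if missing_a or missing_s:
        raise ValueError(
            "community ids do not align between accessibility and SES tables; "
            f"missing from SES: {missing_a[:10]}, missing from access: {missing_s[:10]}"
        )
    ids = sorted(acc.index)
    acc = acc.loc[ids]
    ses = ses.loc[ids]
    keep = ~acc["integrated"].isna()
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-population community(ies)", stacklevel=2)
        acc, ses = acc[keep], ses[keep]

    rows: list[dict] = []
    for mode in modes:
        rows.extend(_fit_block(acc[mode].to_numpy(dtype=float), ses, list(covariates), mode, joint))
    return DeprivationTable(
        rows=pd.DataFrame(rows),
        modes=tuple(modes),
        covariates=tuple(covariates),
        n_communities=int(len(acc)),
    )


def change_analysis(
    access_t1: AccessResult,
    access_t2: AccessResult,
    ses_t1: pd.DataFrame,
    ses_t2: pd.DataFrame,
    covariates: list[str],
    modes: tuple[str, ...] = TABLE_MODES,
    joint: bool = True,
) -> DeprivationTable:
    """Change-on-change analysis between two timepoints.

    Response is A_i(t2) - A_i(t1) per mode; covariates are the SES
    proportion differences.  Communities present at only one timepoint are
    excluded with a warning; a fully disjoint community set is an error.
    """
    common = sorted(
        set(access_t1.table.index)
        & set(access_t2.table.index)
        & set(ses_t1.index)
        & set(ses_t2.index)
    )
    if not common:
        raise ValueError("no community ids shared between the two timepoints")
    all_ids = set(access_t1.table.index) | set(access_t2.table.index)
    dropped = sorted(all_ids - set(common))
    if dropped:
        warnings.warn(
            f"{len(dropped)} community(ies) present at only one timepoint excluded",
            stacklevel=2,
        )
    d_acc = access_t2.table.loc[common, list(modes)] - access_t1.table.loc[common, list(modes)]
    d_ses = ses_t2.loc[common, list(covariates)] - ses_t1.loc[common, list(covariates)]
    delta = DeprivationTable(
        rows=pd.DataFrame(), modes=tuple(modes), covariates=tuple(covariates), n_communities=0
    )
    rows: list[dict] = []
    for mode in modes:
        rows.extend(_fit_block(d_acc[mode].to_numpy(dtype=float), d_ses, list(covariates), mode, joint))
    delta.rows = pd.DataFrame(rows)
    delta.n_communities = len(common)
    delta.meta["kind"] = "change"
    return delta


_VALUE_COLS = ["avg", "p25", "p50", "p75", "se", "p_value"]


def render_tables(table: DeprivationTable, out_dir: str | Path, stem: str = "deprivation") -> dict[str, Path]:
    """Write CSV and aligned-text renderings of a deprivation table.

    Returns the paths written.  ``parse_table`` round-trips the CSV.
    """
    if not table.covariates:
        raise ValueError("empty covariate list; nothing to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{stem}.csv"
    txt_path = out_dir / f"{stem}.txt"

    df = table.rows.copy()
    df.to_csv(csv_path, index=False, float_format="%.10g")

    lines = []
    header = f"{'covariate':<16}{'mode':<18}" + "".join(f"{c:>12}" for c in ["avg", "p25", "p50", "p75"]) + "  stars"
    lines.append(header)
    lines.append("-" * len(header))
    for _, r in df.iterrows():
        lines.append(
            f"{r['covariate']:<16}{r['mode']:<18}"
            + "".join(f"{r[c]:>12.4f}" for c in ["avg", "p25", "p50", "p75"])
            + f"  {r['stars']}"
        )
    lines.append("")
    lines.append(STAR_LEGEND)
    txt_path.write_text("\n".join(lines) + "\n")
    return {"csv": csv_path, "txt": txt_path}


def parse_table(csv_path: str | Path) -> DeprivationTable:
    """Read back a rendered CSV into a DeprivationTable."""
    df = pd.read_csv(csv_path, keep_default_na=False)
    df["stars"] = df["stars"].astype(str)
    for c in _VALUE_COLS:
        df[c] = df[c].astype(float)
    modes = tuple(dict.fromkeys(df["mode"]))
    covs = tuple(dict.fromkeys(df["covariate"]))
    return DeprivationTable(
        rows=df, modes=modes, covariates=covs, n_communities=-1
    )
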