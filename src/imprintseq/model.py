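"""Parent-of-origin expression bias model: fit two paired tests per unit.

`ImprintingModel` holds a :class:`~imprintseq.counts.ParentalCountMatrix`
(aggregated paternal/maternal and ref/alt counts per testing unit, typically
a unique gene fragment) and `.fit()` returns an :class:`ImprintingResults`
carrying, per unit: the paired Wilcoxon signed-rank p/q, the paired
zero-inflated-NB empirical-Bayes likelihood-ratio p/q, the mean paternal
ratio, informative-sample count, direction, a confidence class (high when
both tests pass the FDR threshold, low when exactly one does) and a
reference-bias flag from a paired WSR on aggregated ref vs alt counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counts import ParentalCountMatrix
from .stats import bh_fdr, genomic_inflation, wsr_paired_test
from .zinb import zinb_eb_test

__all__ = [
    "ImprintingModel",
    "ImprintingResults",
    "classify",
    "reference_bias_test",
    "run_power_simulation",
]


def classify(q_wsr, q_zinb, threshold: float = 0.1) -> np.ndarray:
    """Confidence class per unit: high (both q < threshold), low (one), none.

    Missing q values (NaN) count as non-significant.
    """
    q1 = np.nan_to_num(np.asarray(q_wsr, dtype=float), nan=1.0)
    q2 = np.nan_to_num(np.asarray(q_zinb, dtype=float), nan=1.0)
    n_sig = (q1 < threshold).astype(int) + (q2 < threshold).astype(int)
    return np.array(["none", "low", "high"])[n_sig]


def reference_bias_test(
    ref: np.ndarray, alt: np.ndarray, fdr: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flag units whose aggregated ref vs alt counts differ (paired WSR + BH).

    Returns (flag, p, q).  Flagged units are removed from reported imprinted
    sets: a gene whose reads preferentially match the reference genome is an
    alignment artifact, not imprinting.
    """
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    p = np.array([wsr_paired_test(ref[i], alt[i]) for i in range(ref.shape[0])])
    q = bh_fdr(p)
    return q < fdr, p, q


class ImprintingModel:
    """Per-unit paired test of paternal vs maternal aggregated read counts.

    Parameters
    ----------
    data
        Aggregated counts per unit x sample.
    min_informative_fraction
        A unit is tested only if at least this fraction of samples have
        >= 1 read informative for parental origin (inclusive, the default
        0.10 mirrors the "at least 10% of individuals" rule).
    """

    def __init__(
        self,
        data: ParentalCountMatrix,
        min_informative_fraction: float = 0.10,
    ) -> None:
        self.data = data
        self.min_informative_fraction = min_informative_fraction

    def fit(
        self,
        tests: tuple[str, ...] = ("wsr", "zinb"),
        fdr: float = 0.1,
        ref_bias_fdr: float = 0.05,
        zinb_prior_strength: float = 20.0,
    ) -> "ImprintingResults":
        d = self.data
        n_units, n_samples = d.pat.shape
        n_inf = d.n_informative
        tested = n_inf >= self.min_informative_fraction * n_samples

        p_wsr = np.full(n_units, np.nan)
        p_zinb = np.full(n_units, np.nan)
        zinb_conv = np.ones(n_units, dtype=bool)
        if "wsr" in tests:
            for i in np.where(tested)[0]:
                inf = (d.pat[i] + d.mat[i]) >= 1
                p_wsr[i] = wsr_paired_test(d.pat[i][inf], d.mat[i][inf])
        if "zinb" in tests and tested.any():
            fitres = zinb_eb_test(
                d.pat[tested], d.mat[tested], prior_strength=zinb_prior_strength
            )
            p_zinb[tested] = fitres.p
            zinb_conv[tested] = fitres.converged

        q_wsr = np.full(n_units, np.nan)
        q_zinb = np.full(n_units, np.nan)
        if np.isfinite(p_wsr).any():
            q_wsr[tested] = bh_fdr(p_wsr[tested])
        if np.isfinite(p_zinb).any():
            q_zinb[tested] = bh_fdr(p_zinb[tested])

        ratio = d.pat_ratio()
        flags, p_rb, q_rb = reference_bias_test(d.ref, d.alt, fdr=ref_bias_fdr)
        table = pd.DataFrame(
            {
                "unit_id": d.unit_ids,
                "n_informative": n_inf,
                "tested": tested,
                "mean_pat_ratio": ratio,
                "direction": np.where(ratio > 0.5, "paternal", "maternal"),
                "p_wsr": p_wsr,
                "q_wsr": q_wsr,
                "p_zinb": p_zinb,
                "q_zinb": q_zinb,
                "zinb_converged": zinb_conv,
                "confidence": classify(q_wsr, q_zinb, threshold=fdr),
                "p_ref_bias": p_rb,
                "q_ref_bias": q_rb,
                "ref_bias_flag": flags,
            }
        )
        return ImprintingResults(self, table, fdr=fdr)


class ImprintingResults:
    """Results container: per-unit table, inflation factors, summaries."""

    def __init__(self, model: ImprintingModel, table: pd.DataFrame, fdr: float) -> None:
        self.model = model
        self.table = table
        self.fdr = fdr

    @property
    def n_tested(self) -> int:
        return int(self.table["tested"].sum())

    def n_significant(self, test: str = "wsr") -> int:
        return int((self.table[f"q_{test}"] < self.fdr).sum())

    def lambda_gc(self, test: str = "wsr") -> float:
        p = self.table.loc[self.table["tested"], f"p_{test}"].dropna().values
        return genomic_inflation(p)

    def significant(self, confidence: str = "any") -> pd.DataFrame:
        """Significant units, reference-biased ones removed.

        ``confidence``: 'high', 'low' or 'any' (= high or low).
        """
        t = self.table
        keep = ~t["ref_bias_flag"]
        if confidence == "any":
            keep &= t["confidence"].isin(["high", "low"])
        else:
            keep &= t["confidence"] == confidence
        return t[keep].reset_index(drop=True)

    def per_gene(self, ugf_gene_ids: pd.Series) -> pd.DataFrame:
        """One row per gene: the unit with the smallest WSR p among its UGFs.

        ``ugf_gene_ids`` maps unit_id -> comma-joined gene ids (as produced
        by :func:`imprintseq.annotation.build_ugfs`).
        """
        t = self.table.copy()
        t["gene_ids"] = t["unit_id"].map(ugf_gene_ids)
        t = t[t["gene_ids"].notna()]
        t = t.assign(gene_id=t["gene_ids"].str.split(",")).explode("gene_id")
        t = t.sort_values("p_wsr", kind="stable")
        return t.drop_duplicates("gene_id").reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Parent-of-origin expression bias",
            "=" * 40,
            f"units tested        {self.n_tested} / {len(self.table)}",
            f"FDR threshold       {self.fdr:g}",
        ]
        for test in ("wsr", "zinb"):
            if self.table[f"p_{test}"].notna().any():
                try:
                    lam = f"{self.lambda_gc(test):.4f}"
                except ValueError:
                    lam = "n/a"
                lines.append(
                    f"{test:4s}: significant {self.n_significant(test):4d}   lambda_gc {lam}"
                )
        counts = self.table.loc[self.table["tested"], "confidence"].value_counts()
        lines.append(
            "confidence          "
            + "  ".join(f"{k}={counts.get(k, 0)}" for k in ("high", "low", "none"))
        )
        lines.append(f"ref-bias flagged    {int(self.table['ref_bias_flag'].sum())}")
        return "\n".join(lines)


def run_power_simulation(
    config,
    n_samples_grid: tuple[int, ...] = (20, 50, 138),
    q_threshold: float = 0.1,
    seed: int | None = None,
    high_expression_level: float = 50.0,
) -> pd.DataFrame:
    """Sensitivity and realized FDR of both tests over a sample-size grid.

    For each grid point the gene-level benchmark scheme is simulated at the
    given cohort size and both tests are run; sensitivity is reported among
    truly imprinted genes (overall and restricted to expression level >=
    ``high_expression_level``) and realized FDR among calls at
    ``q < q_threshold``.
    """
    from .simulate import simulate_gene_counts

    rows = []
    for n in n_samples_grid:
        cfg = config.with_(n_samples=n, seed=config.seed if seed is None else seed)
        rng = np.random.default_rng((cfg.seed, n, 7))
        pat, mat, genes = simulate_gene_counts(cfg, rng)
        pcm = ParentalCountMatrix(
            unit_ids=genes["gene_id"].values,
            sample_ids=np.arange(n),
            pat=pat,
            mat=mat,
            ref=pat,
            alt=mat,
        )
        res = ImprintingModel(pcm).fit(fdr=q_threshold)
        truth = genes["is_imprinted"].values
        high = genes["level"].values >= high_expression_level
        for test in ("wsr", "zinb"):
            q = res.table[f"q_{test}"].values
            called = q < q_threshold
            n_called = int(called.sum())
            tp = int((called & truth).sum())
            sens = tp / truth.sum() if truth.sum() else np.nan
            denom_high = (truth & high).sum()
            sens_high = (
                int((called & truth & high).sum()) / denom_high if denom_high else np.nan
            )
            fdp = (n_called - tp) / n_called if n_called else 0.0
            rows.append(
                {
                    "n_samples": n,
                    "test": test,
                    "n_called": n_called,
                    "sensitivity": sens,
                    "sensitivity_high_expr": sens_high,
                    "realized_fdr": fdp,
                }
            )
    return pd.DataFrame(rows)
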