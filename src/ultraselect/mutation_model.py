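"""Neighbor-dependent, covariate-adjusted, regionally rescaled mutation model.

The neutral probability that a given alternate allele appears as a rare
variant at a site is modelled in three stages, each fitted to putatively
neutral sites only:

1. *Context rates*: relative frequencies of each substitution a -> b (and of
   no substitution, a -> a) conditional on the heptamer context — the focal
   base plus three flanking bases on each side (4^8 context x outcome cells).
2. *Covariate adjustment*: a linear-logistic model of per-(site, allele)
   rare-variant presence on four covariates — the logit of the raw context
   rate, log sequencing coverage, fractional G+C content in a 200 bp window,
   and a CpG-island indicator.
3. *Regional rescaling*: a free intercept (local scaling factor, on the
   logit scale) fitted in sliding windows along each chromosome with the
   stage-2 logit as a fixed-coefficient-one offset.

The composed prediction fills the per-site, per-allele probabilities P_i^(j)
consumed by the estimator.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

from .errors import ConfigError, NumericalError, SchemaError, ValidationError
from .io_genomics import NUCLEOTIDES, SiteTable

#: pseudocount added to every outcome count before normalization, so that no
#: context assigns probability zero to an unobserved substitution
PSEUDOCOUNT = 0.5

COVARIATE_NAMES = ["intercept", "logit_raw_rate", "log_coverage", "gc_frac", "cpg_island"]


# ---------------------------------------------------------------------------
# Stage 1: heptamer context rates


class ContextRateTable:
    """Per-heptamer outcome distributions with k-mer fallback.

    For each observed 7-mer context the four outcome frequencies (three
    substitutions plus "no mutation") sum to one. Contexts unseen in
    training fall back to the 3-mer (one flank each side) rate for the same
    substitution, then to the reference-base marginal.
    """

    def __init__(
        self,
        rates7: pd.DataFrame,
        rates3: pd.DataFrame,
        rates1: pd.DataFrame,
        counts7: pd.DataFrame | None = None,
    ):
        # each frame: columns context, ref, alt, rate ("alt" == ref encodes a->a)
        self.rates7 = rates7
        self.rates3 = rates3
        self.rates1 = rates1
        # raw (pre-pseudocount) counts, kept when fitted from data so the
        # covariate regression can use leave-one-out rates
        self.counts7 = counts7
        self._lut7 = rates7.set_index(["context", "alt"])["rate"]
        self._lut3 = rates3.set_index(["context", "alt"])["rate"]
        self._lut1 = rates1.set_index(["context", "alt"])["rate"]

    def rate(self, context: str, alt: str, fallback: bool = True) -> float:
        """Relative frequency of ``context[3] -> alt`` (alt == center: no mutation)."""
        key = (context, alt)
        if key in self._lut7.index:
            return float(self._lut7.loc[key])
        if not fallback:
            raise NumericalError(f"unseen context {context!r} with fallback disabled")
        key3 = (context[2:5], alt)
        if key3 in self._lut3.index:
            return float(self._lut3.loc[key3])
        return float(self._lut1.loc[(context[3], alt)])

    def outcome_distribution(self, context: str) -> dict[str, float]:
        return {b: self.rate(context, b) for b in NUCLEOTIDES}

    def loo_lookup(
        self, contexts: pd.Series, alts: pd.Series, Y: np.ndarray
    ) -> np.ndarray:
        """Leave-one-out rates for training rows: each row's own outcome is
        removed from its context's counts before normalization, so a site's
        rare-variant indicator never leaks into its own covariate."""
        if self.counts7 is None:
            raise ValidationError(
                "leave-one-out rates require a table fitted from data (counts kept)"
            )
        keys = pd.MultiIndex.from_arrays([contexts, alts])
        lut_c = self.counts7.set_index(["context", "alt"])["count"]
        lut_t = self.counts7.groupby("context")["count"].sum()
        c = lut_c.reindex(keys).to_numpy()
        t = lut_t.reindex(pd.Index(contexts)).to_numpy()
        if np.isnan(c).any() or np.isnan(t).any():
            raise ValidationError("leave-one-out rates requested for unseen contexts")
        Y = np.asarray(Y, dtype=float)
        return (c - Y + PSEUDOCOUNT) / (t - 1.0 + 4 * PSEUDOCOUNT)

    def lookup(self, contexts: pd.Series, alts: pd.Series, fallback: bool = True) -> np.ndarray:
        """Vectorized rate lookup for aligned context/alt vectors."""
        keys = pd.MultiIndex.from_arrays([contexts, alts])
        out = self._lut7.reindex(keys).to_numpy()
        miss = np.isnan(out)
        if miss.any():
            if not fallback:
                bad = sorted(set(contexts[miss]))
                raise NumericalError(f"unseen contexts with fallback disabled: {bad[:10]}")
            keys3 = pd.MultiIndex.from_arrays([contexts[miss].str[2:5], alts[miss]])
            out3 = self._lut3.reindex(keys3).to_numpy()
            out[miss] = out3
            miss = np.isnan(out)
            if miss.any():
                keys1 = pd.MultiIndex.from_arrays([contexts[miss].str[3], alts[miss]])
                out[miss] = self._lut1.reindex(keys1).to_numpy()
        return out

    def write(self, path: str) -> None:
        self.rates7.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, path: str) -> "ContextRateTable":
        rates7 = pd.read_csv(path, sep="\t")
        missing = {"context", "ref", "alt", "rate"} - set(rates7.columns)
        if missing:
            raise SchemaError(f"{path}: missing columns {sorted(missing)}")
        return cls(rates7, *_marginalize(rates7))


def _normalize_counts(counts: pd.DataFrame, ctx_col: str) -> pd.DataFrame:
    """Counts (ctx_col, ref, alt, count) -> rates summing to 1 per context."""
    counts = counts.copy()
    counts["count"] = counts["count"] + PSEUDOCOUNT
    total = counts.groupby(ctx_col)["count"].transform("sum")
    counts["rate"] = counts["count"] / total
    out = counts[[ctx_col, "ref", "alt", "rate"]].rename(columns={ctx_col: "context"})
    return out.reset_index(drop=True)


def _marginalize(rates7: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate 7-mer rates into 3-mer and single-base fallback tables."""
    df = rates7.copy()
    df["ctx3"] = df["context"].str[2:5]
    g3 = df.groupby(["ctx3", "ref", "alt"], as_index=False)["rate"].mean()
    g3 = g3.rename(columns={"ctx3": "context"})
    # renormalize per context
    tot = g3.groupby("context")["rate"].transform("sum")
    g3["rate"] = g3["rate"] / tot
    g1 = df.groupby(["ref", "alt"], as_index=False)["rate"].mean()
    g1["context"] = g1["ref"]
    tot1 = g1.groupby("context")["rate"].transform("sum")
    g1["rate"] = g1["rate"] / tot1
    return g3[["context", "ref", "alt", "rate"]], g1[["context", "ref", "alt", "rate"]]


def fit_context_rates(neutral: SiteTable) -> ContextRateTable:
    """Count substitution outcomes per heptamer and normalize to frequencies.

    For each context the outcome counts are: one count per (site, allele)
    rare variant for each substitution, and one count per variant-free site
    for "no mutation". A pseudocount keeps every outcome strictly positive.
    """
    ret = neutral.retained
    if len(ret) == 0:
        raise ValidationError("empty neutral table")
    # substitution counts per (context, alt)
    sub = (
        ret.groupby(["context7", "ref", "alt"], as_index=False)["Y"]
        .sum()
        .rename(columns={"context7": "context", "Y": "count"})
    )
    # "no mutation" counts: sites with no rare variant at all
    per_site = ret.groupby(["chrom", "pos0"]).agg(
        context=("context7", "first"), ref=("ref", "first"), any_y=("Y", "max")
    )
    no_mut = (
        per_site[per_site["any_y"] == 0]
        .groupby(["context", "ref"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    no_mut["alt"] = no_mut["ref"]
    # ensure all 4 outcomes exist for every observed context
    contexts = per_site[["context", "ref"]].drop_duplicates()
    full = contexts.merge(pd.DataFrame({"alt": list(NUCLEOTIDES)}), how="cross")
    counts = full.merge(
        pd.concat([sub, no_mut[["context", "ref", "alt", "count"]]]),
        on=["context", "ref", "alt"],
        how="left",
    ).fillna({"count": 0})
    rates7 = _normalize_counts(counts, "context")
    counts7 = counts[["context", "ref", "alt", "count"]].reset_index(drop=True)
    return ContextRateTable(rates7, *_marginalize(rates7), counts7=counts7)


# ---------------------------------------------------------------------------
# Stage 2: covariate model


@dataclass
class CovariateModel:
    """Linear-logistic adjustment of the raw context rate.

    ``coefficients`` are ordered as :data:`COVARIATE_NAMES`:
    intercept, logit of the raw context rate, log(coverage + 1),
    G+C fraction, CpG-island indicator.
    """

    coefficients: np.ndarray
    loglik: float = float("nan")
    n_obs: int = 0
    seed: int | None = None
    sample_fraction: float = 1.0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (5,):
            raise ValidationError("covariate model requires 5 coefficients")
        if not np.all(np.isfinite(self.coefficients)):
            raise NumericalError("non-finite covariate coefficients")

    def linear_predictor(self, design: np.ndarray) -> np.ndarray:
        return design @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "names": COVARIATE_NAMES,
            "coefficients": self.coefficients.tolist(),
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "seed": self.seed,
            "sample_fraction": self.sample_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateModel":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            loglik=d.get("loglik", float("nan")),
            n_obs=d.get("n_obs", 0),
            seed=d.get("seed"),
            sample_fraction=d.get("sample_fraction", 1.0),
        )

    @classmethod
    def identity(cls) -> "CovariateModel":
        """Pass-through model: coefficient one on the raw-rate logit."""
        return cls(coefficients=np.array([0.0, 1.0, 0.0, 0.0, 0.0]))


def _design_matrix(df: pd.DataFrame, raw_rate: np.ndarray) -> np.ndarray:
    eps = 1e-12
    raw = np.clip(raw_rate, eps, 1 - eps)
    return np.column_stack(
        [
            np.ones(len(df)),
            logit(raw),
            np.log(df["coverage"].to_numpy() + 1.0),
            df["gc_frac"].to_numpy(),
            df["cpg_island"].to_numpy().astype(float),
        ]
    )


def fit_covariate_model(
    neutral: SiteTable,
    raw: ContextRateTable,
    sample_fraction: float = 0.01,
    seed: int = 0,
) -> CovariateModel:
    """Binomial-logistic fit of rare-variant presence on the four covariates.

    A simple random sample of neutral *sites* (all three allele rows of a
    sampled site are kept together) of size ``sample_fraction`` is used for
    efficiency; the fit is deterministic given ``seed``.
    """
    if not 0 < sample_fraction <= 1:
        raise ConfigError("sample_fraction must be in (0, 1]")
    ret = neutral.retained
    for col in ("coverage", "gc_frac", "cpg_island"):
        if ret[col].isna().any():
            raise SchemaError(f"missing covariate values in column {col!r}")
    sites = ret[["chrom", "pos0"]].drop_duplicates()
    rng = np.random.default_rng(seed)
    if sample_fraction < 1:
        take = rng.random(len(sites)) < sample_fraction
        sites = sites[take]
    df = ret.merge(sites, on=["chrom", "pos0"])
    if len(df) == 0:
        raise ValidationError("no neutral sites sampled; increase sample_fraction")
    if raw.counts7 is not None:
        # leave-one-out covariate: prevents each site's indicator from
        # inflating the coefficient on its own context rate
        raw_rate = raw.loo_lookup(df["context7"], df["alt"], df["Y"].to_numpy())
    else:
        raw_rate = raw.lookup(df["context7"], df["alt"])
    X = _design_matrix(df, raw_rate)
    y = df["Y"].to_numpy().astype(float)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=200)
        except Exception as exc:  # perfect separation, singular design
            raise NumericalError(f"covariate model failed to fit: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        bad = [COVARIATE_NAMES[i] for i in np.where(~np.isfinite(res.params))[0]]
        raise NumericalError(f"non-finite coefficient(s) for covariate(s): {bad}")
    return CovariateModel(
        coefficients=res.params,
        loglik=float(res.llf),
        n_obs=len(df),
        seed=seed,
        sample_fraction=sample_fraction,
    )


# ---------------------------------------------------------------------------
# Stage 3: regional rescaling


@dataclass
class RegionalScaler:
    """Per-window logit-scale intercepts (local mutation-rate scaling).

    Windows of length ``window`` start every ``step`` bp on each chromosome.
    A site may fall in up to ``window // step`` windows; its scaling factor
    is the arithmetic mean of the intercepts of the covering windows.
    """

    table: pd.DataFrame  # columns: chrom, win_start, intercept
    window: int = 150_000
    step: int = 50_000

    def __post_init__(self):
        if self.window <= 0 or self.step <= 0:
            raise ValidationError("window and step must be positive")
        self._by_chrom = {
            chrom: grp.sort_values("win_start")["intercept"].to_numpy()
            for chrom, grp in self.table.groupby("chrom")
        }

    def intercept_at(self, chroms: pd.Series, positions: np.ndarray) -> np.ndarray:
        """Mean intercept of the windows covering each (chrom, pos)."""
        positions = np.asarray(positions)
        out = np.zeros(len(positions), dtype=float)
        chrom_arr = np.asarray(chroms)
        for chrom, inters in self._by_chrom.items():
            mask = chrom_arr == chrom
            if not mask.any():
                continue
            pos = positions[mask]
            nwin = len(inters)
            # covering windows k: k*step <= pos < k*step + window
            hi = np.minimum(pos // self.step, nwin - 1)
            lo = np.maximum((pos - self.window) // self.step + 1, 0)
            lo = np.minimum(lo, nwin - 1)
            cum = np.concatenate([[0.0], np.cumsum(inters)])
            out[mask] = (cum[hi + 1] - cum[lo]) / (hi - lo + 1)
        unknown = ~np.isin(chrom_arr, list(self._by_chrom))
        if unknown.any():
            out[unknown] = 0.0  # no local information: identity scaling
        return out

    @classmethod
    def identity(cls, chroms: list[str]) -> "RegionalScaler":
        tbl = pd.DataFrame({"chrom": chroms, "win_start": 0, "intercept": 0.0})
        return cls(table=tbl)

    def write(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read(cls, path: str, window: int = 150_000, step: int = 50_000) -> "RegionalScaler":
        return cls(table=pd.read_csv(path, sep="\t"), window=window, step=step)


def window_starts(chrom_length: int, window: int, step: int) -> np.ndarray:
    """Window start positions: every ``step`` bp, last window clipped at the
    chromosome end."""
    if window <= 0 or step <= 0:
        raise ValidationError("window and step must be positive")
    n = max(1, (max(chrom_length - window, 0)) // step + 1)
    starts = np.arange(n) * step
    # guarantee full coverage when window < step
    while starts[-1] + window < chrom_length:
        starts = np.append(starts, starts[-1] + step)
    return starts


def fit_regional_scalers(
    neutral: SiteTable,
    adjusted_logits: np.ndarray,
    window: int = 150_000,
    step: int = 50_000,
    min_sites: int = 100,
) -> RegionalScaler:
    """Fit one free logit-scale intercept per sliding window.

    Each window's logistic regression uses the stage-2 adjusted logit as an
    offset with fixed coefficient one, so the intercept is a local scaling
    factor. Windows with fewer than ``min_sites`` neutral sites inherit the
    chromosome-wide intercept.
    """
    ret = neutral.retained
    if len(ret) != len(adjusted_logits):
        raise ValidationError("adjusted_logits must align with retained rows")
    y = ret["Y"].to_numpy().astype(float)
    pos = ret["pos0"].to_numpy()
    rows = []
    for chrom in ret["chrom"].unique():
        cmask = (ret["chrom"] == chrom).to_numpy()
        cpos = pos[cmask]
        cy = y[cmask]
        coff = np.asarray(adjusted_logits)[cmask]
        chrom_len = int(cpos.max()) + 1
        chrom_intercept = _fit_offset_intercept(cy, coff)
        for start in window_starts(chrom_len, window, step):
            wmask = (cpos >= start) & (cpos < start + window)
            n_sites_w = wmask.sum() // 3
            if n_sites_w >= min_sites:
                inter = _fit_offset_intercept(cy[wmask], coff[wmask])
            else:
                inter = chrom_intercept
            rows.append((chrom, int(start), inter))
    tbl = pd.DataFrame(rows, columns=["chrom", "win_start", "intercept"])
    return RegionalScaler(table=tbl, window=window, step=step)


def _fit_offset_intercept(y: np.ndarray, offset: np.ndarray) -> float:
    """MLE of b in logit(p) = offset + b, by Newton iteration."""
    if len(y) == 0:
        return 0.0
    b = 0.0
    for _ in range(50):
        p = expit(offset + b)
        grad = float(np.sum(y - p))
        hess = float(np.sum(p * (1 - p)))
        if hess <= 0:
            break
        delta = grad / hess
        b += delta
        if abs(delta) < 1e-10:
            break
    return float(np.clip(b, -20, 20))


# ---------------------------------------------------------------------------
# Composition


def adjusted_logits(
    df: pd.DataFrame,
    rates: ContextRateTable,
    cov: CovariateModel,
    loo: bool = False,
) -> np.ndarray:
    """Stage-1 + stage-2 logit for each (site, alt) row (no regional term).

    ``loo=True`` (training data only) uses leave-one-out context rates so
    the regional intercepts are calibrated against leak-free covariates.
    """
    if loo:
        raw_rate = rates.loo_lookup(df["context7"], df["alt"], df["Y"].to_numpy())
    else:
        raw_rate = rates.lookup(df["context7"], df["alt"])
    X = _design_matrix(df, raw_rate)
    return cov.linear_predictor(X)


def predict_rates(
    table: SiteTable,
    rates: ContextRateTable,
    cov: CovariateModel,
    scaler: RegionalScaler | None = None,
) -> SiteTable:
    """Fill P_i^(j) for every retained (site, alt) row.

    Pipeline: heptamer rate -> covariate logistic -> regional intercept
    added on the logit scale -> inverse logit.
    """
    out = table.copy()
    mask = ~out.df["excluded"]
    df = out.df[mask]
    eta = adjusted_logits(df, rates, cov)
    if scaler is not None:
        eta = eta + scaler.intercept_at(df["chrom"], df["pos0"].to_numpy())
    P = expit(eta)
    # cap each per-allele rate just below 1/3 so the summed per-site rate
    # stays below 1 even for sparsely observed contexts; realistic rates
    # are orders of magnitude smaller, so the cap never binds in practice
    eps = np.finfo(float).tiny
    out.df.loc[mask, "P"] = np.clip(P, eps, 1.0 / 3.0 - 1e-9)
    out.validate()
    return out


def calibration_report(table: SiteTable, bins: int = 10) -> pd.DataFrame:
    """Observed rare-variant fraction vs mean predicted P by quantile bin.

    Returns a frame with one row per bin: mean predicted P, observed
    fraction (mean Y), and the number of (site, alt) pairs in the bin.
    """
    ret = table.retained
    if ret["P"].isna().any():
        raise ValidationError("P not filled; run predict_rates first")
    if bins < 1:
        raise ConfigError("bins must be >= 1")
    if bins == 1:
        grp = pd.Series(0, index=ret.index)
    else:
        grp = pd.qcut(ret["P"].rank(method="first"), q=bins, labels=False)
    rep = (
        ret.assign(_bin=grp)
        .groupby("_bin")
        .agg(mean_P=("P", "mean"), observed=("Y", "mean"), count=("Y", "size"))
        .reset_index()
        .rename(columns={"_bin": "bin"})
    )
    return rep


# ---------------------------------------------------------------------------
# Model bundle serialization


@dataclass
class MutationModel:
    """The fitted three-stage model, serializable as a directory bundle."""

    rates: ContextRateTable
    covariates: CovariateModel
    scaler: RegionalScaler
    metadata: dict = field(default_factory=dict)

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        self.rates.write(os.path.join(directory, "context_rates.tsv"))
        with open(os.path.join(directory, "covariates.json"), "w") as fh:
            json.dump(self.covariates.to_dict(), fh, indent=1)
        self.scaler.write(os.path.join(directory, "regional.tsv"))
        manifest = dict(self.metadata)
        manifest.update({"window": self.scaler.window, "step": self.scaler.step})
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory: str) -> "MutationModel":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        rates = ContextRateTable.read(os.path.join(directory, "context_rates.tsv"))
        with open(os.path.join(directory, "covariates.json")) as fh:
            cov = CovariateModel.from_dict(json.load(fh))
        scaler = RegionalScaler.read(
            os.path.join(directory, "regional.tsv"),
            window=manifest.get("window", 150_000),
            step=manifest.get("step", 50_000),
        )
        return cls(rates=rates, covariates=cov, scaler=scaler, metadata=manifest)


def fit_mutation_model(
    neutral: SiteTable,
    sample_fraction: float = 0.01,
    seed: int = 0,
    window: int = 150_000,
    step: int = 50_000,
    min_sites: int = 100,
) -> MutationModel:
    """Fit all three stages on a neutral SiteTable."""
    rates = fit_context_rates(neutral)
    cov = fit_covariate_model(neutral, rates, sample_fraction=sample_fraction, seed=seed)
    eta = adjusted_logits(neutral.retained, rates, cov, loo=True)
    scaler = fit_regional_scalers(neutral, eta, window=window, step=step, min_sites=min_sites)
    meta = {"seed": seed, "sample_fraction": sample_fraction, "n_neutral_sites": neutral.n_sites}
    return MutationModel(rates=rates, covariates=cov, scaler=scaler, metadata=meta)
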