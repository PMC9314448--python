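"""Genome-wide accounting of ultraselected sites.

Given per-category depletion estimates lambda_s and site counts for a
mutually exclusive, exhaustive partition of the genome, this module
computes the background-adjusted expected number of ultraselected sites
per category, their proportions and fold enrichments, and the expected
number of de novo strongly deleterious mutations per potential zygote
(expected sites times twice the per-generation mutation rate, the factor
two allowing for heterozygous mutations on either haplotype).

The background correction conservatively subtracts the lambda_s of a
putatively unconstrained category (e.g. nonconserved introns) from every
category, flooring negative adjusted values at zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class CategoryRow:
    """One genome partition category: depletion estimate and site count."""

    name: str
    lambda_s: float
    stderr: float
    n_sites: float
    is_background: bool = False

    def __post_init__(self):
        if self.n_sites <= 0:
            raise ValidationError(f"{self.name}: n_sites must be positive")
        if self.stderr < 0:
            raise ValidationError(f"{self.name}: negative stderr")


#: Published genome-wide partition of the human autosomes (gnomAD v3,
#: 71,702 genomes): per-category lambda_s estimates, standard errors and
#: site counts. Site counts in bases. Background for the conservative
#: correction: nonconserved introns.
GNOMAD_V3_GENOME_WIDE: list[CategoryRow] = [
    CategoryRow("CDS", 0.148, 0.0004, 33.8e6),
    CategoryRow("5' UTR", -0.161, 0.0006, 8.2e6),
    CategoryRow("3' UTR", 0.028, 0.0002, 36.1e6),
    CategoryRow("splice", 0.464, 0.0012, 0.8e6),
    CategoryRow("nonconserved lncRNA", 0.009, 0.0001, 453.6e6),
    CategoryRow("conserved lncRNA", 0.055, 0.0003, 23.3e6),
    CategoryRow("nonconserved intron", 0.009, 0.00009, 972.6e6),
    CategoryRow("conserved intron", 0.058, 0.0002, 44.3e6),
    CategoryRow("nonconserved intergenic", 0.003, 0.00001, 1255.5e6),
    CategoryRow("conserved intergenic", 0.048, 0.0002, 46.9e6),
]

DEFAULT_BACKGROUND = "nonconserved intron"


@dataclass
class PartitionAccounting:
    """Per-category accounting table plus totals."""

    table: pd.DataFrame
    totals: dict
    background: str
    mu: float

    def write(self, path_tsv: str, path_totals: str | None = None) -> None:
        self.table.to_csv(path_tsv, sep="\t", index=False, float_format="%.10g")
        if path_totals is not None:
            with open(path_totals, "w") as fh:
                json.dump(self.totals, fh, indent=1)


def build_accounting(
    rows: Iterable[CategoryRow],
    background_name: str = DEFAULT_BACKGROUND,
    mu: float = 1.2e-8,
) -> PartitionAccounting:
    """Background-subtract, count expected ultraselected sites, and convert
    to expected strongly deleterious mutations per potential zygote.

    Per category: adjusted lambda = max(lambda_s - lambda_background, 0);
    expected sites = adjusted lambda x n_sites; expected strongly
    deleterious mutations = expected sites x 2 mu; fold enrichment =
    (category share of expected ultraselected sites) / (category share of
    all sites). Totals are computed from unrounded values.
    """
    rows = list(rows)
    names = [r.name for r in rows]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate category names")
    bg = [r for r in rows if r.name == background_name]
    if not bg:
        raise ValidationError(f"background category {background_name!r} not found")
    lam_bg = bg[0].lambda_s

    df = pd.DataFrame(
        {
            "name": names,
            "lambda_s": [r.lambda_s for r in rows],
            "stderr": [r.stderr for r in rows],
            "n_sites": [r.n_sites for r in rows],
        }
    )
    total_n = df["n_sites"].sum()
    df["prop_sites"] = df["n_sites"] / total_n
    df["adj_lambda"] = np.where(df["name"] == background_name, 0.0,
                                np.maximum(df["lambda_s"] - lam_bg, 0.0))
    df["exp_sites"] = df["adj_lambda"] * df["n_sites"]
    total_exp = df["exp_sites"].sum()
    if total_exp > 0:
        df["exp_prop"] = df["exp_sites"] / total_exp
    else:
        df["exp_prop"] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        df["fold_enrich"] = df["exp_prop"] / df["prop_sites"]
    df["exp_deleterious"] = df["exp_sites"] * 2.0 * mu

    totals = {
        "n_sites": float(total_n),
        "exp_sites": float(total_exp),
        "exp_ultraselected_fraction": float(total_exp / total_n),
        "exp_deleterious": float(total_exp * 2.0 * mu),
        "background": background_name,
        "mu": mu,
    }
    return PartitionAccounting(table=df, totals=totals, background=background_name, mu=mu)


def propagate_errors(
    rows: Iterable[CategoryRow],
    background_name: str = DEFAULT_BACKGROUND,
    mu: float = 1.2e-8,
) -> pd.DataFrame:
    """Standard errors of adjusted lambda and derived counts, assuming
    independent category and background estimates (quadrature).

    The background row's adjusted lambda is identically zero, so its
    propagated error is zero. The frame carries a ``total`` row whose
    expected-site error combines categories in quadrature.
    """
    rows = list(rows)
    bg = [r for r in rows if r.name == background_name]
    if not bg:
        raise ValidationError(f"background category {background_name!r} not found")
    se_bg = bg[0].stderr
    recs = []
    for r in rows:
        if r.name == background_name:
            se_adj = 0.0
        else:
            se_adj = float(np.hypot(r.stderr, se_bg))
        recs.append(
            {
                "name": r.name,
                "se_adj_lambda": se_adj,
                "se_exp_sites": se_adj * r.n_sites,
                "se_exp_deleterious": se_adj * r.n_sites * 2.0 * mu,
            }
        )
    df = pd.DataFrame(recs)
    total_sites_se = float(np.sqrt(np.sum(df["se_exp_sites"] ** 2)))
    total = {
        "name": "total",
        "se_adj_lambda": float("nan"),
        "se_exp_sites": total_sites_se,
        "se_exp_deleterious": total_sites_se * 2.0 * mu,
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def read_category_rows(path: str) -> list[CategoryRow]:
    """Read CategoryRows from a headered TSV (name, lambda_s, stderr, n_sites)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "lambda_s", "stderr", "n_sites"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [
        CategoryRow(
            name=str(r.name),
            lambda_s=float(r.lambda_s),
            stderr=float(r.stderr),
            n_sites=float(r.n_sites),
        )
        for r in df.itertuples(index=False)
    ]
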