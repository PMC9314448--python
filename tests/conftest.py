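import numpy as np
import pandas as pd
import pytest

from ultraselect.io_genomics import SITE_TABLE_COLUMNS, SiteTable, alt_alleles


def make_site_table(
    P,
    Y=None,
    ref="A",
    context=None,
    coverage=30.0,
    gc_frac=0.4,
    cpg_island=False,
    chrom="t",
) -> SiteTable:
    """Build a valid in-memory SiteTable from flat per-(site, alt) arrays.

    ``P`` (and ``Y`` if given) must have length 3 * M; sites are laid out on
    consecutive positions of a synthetic chromosome.
    """
    P = np.asarray(P, dtype=float)
    if len(P) % 3 != 0:
        raise ValueError("need 3 alt rows per site")
    M = len(P) // 3
    Y = np.zeros(3 * M, dtype=np.int64) if Y is None else np.asarray(Y, dtype=np.int64)
    if context is None:
        context = ref * 7
    context = np.broadcast_to(np.asarray(context, dtype=object), 3 * M)
    alts = np.tile(np.array(alt_alleles(ref), dtype=object), M)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos0": np.repeat(np.arange(M), 3),
            "ref": ref,
            "alt": alts,
            "context7": context,
            "Y": Y,
            "common": False,
            "coverage": np.broadcast_to(np.asarray(coverage, dtype=float), 3 * M),
            "gc_frac": np.broadcast_to(np.asarray(gc_frac, dtype=float), 3 * M),
            "cpg_island": np.broadcast_to(np.asarray(cpg_island), 3 * M),
            "excluded": False,
            "reason": "",
            "P": P,
        }
    )[SITE_TABLE_COLUMNS]
    return SiteTable(df)


def write_fasta(path, sequences: dict[str, str]) -> str:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)


@pytest.fixture(scope="session")
def genome_fixture(tmp_path_factory):
    """A 60 kb synthetic genome with BED tracks and per-site coverage."""
    from ultraselect.simulate import synthetic_genome

    outdir = tmp_path_factory.mktemp("genome")
    return synthetic_genome(60_000, seed=101, outdir=str(outdir))
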