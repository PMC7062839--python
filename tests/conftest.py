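import pathlib

import numpy as np
import pandas as pd
import pytest

import condfdr as cf

DATA = pathlib.Path(__file__).parent / "data"


@pytest.fixture
def data_dir():
    return DATA


def make_sumstats(snp_ids, chrom="1", pos=None, beta=0.1, se=0.05, p=0.5,
                  ea="A", oa="G", info=np.nan, maf=0.3, **kw):
    """Build a small validated SumstatsTable from scalars or per-SNP arrays."""
    n = len(snp_ids)

    def arr(v):
        return np.broadcast_to(np.asarray(v), (n,)).copy()

    df = pd.DataFrame({
        "snp_id": snp_ids,
        "chrom": arr(chrom).astype(str),
        "pos": arr(pos if pos is not None else np.arange(1, n + 1) * 1000),
        "effect_allele": arr(ea).astype(str),
        "other_allele": arr(oa).astype(str),
        "beta": arr(beta).astype(float),
        "se": arr(se).astype(float),
        "p": arr(p).astype(float),
        "info": arr(info).astype(float),
        "maf": arr(maf).astype(float),
    })
    return cf.SumstatsTable(df, **kw)


def make_merged(p1, p2, chrom="1", pos=None, maf=0.3, beta1=0.1, beta2=0.1):
    n = len(p1)
    ids = [f"rs{i}" for i in range(n)]

    def arr(v):
        return np.broadcast_to(np.asarray(v), (n,)).copy()

    df = pd.DataFrame({
        "snp_id": ids, "chrom": arr(chrom).astype(str),
        "pos": arr(pos if pos is not None else np.arange(1, n + 1) * 1000),
        "ea": "A", "oa": "G",
        "beta1": arr(beta1).astype(float), "se1": 0.05, "p1": np.asarray(p1, float),
        "beta2": arr(beta2).astype(float), "se2": 0.05, "p2": np.asarray(p2, float),
        "maf": arr(maf).astype(float),
    })
    return cf.MergedPair(df)


def make_panel(dosages, chrom=None, pos=None, snp_ids=None, haplotypes=None):
    """Panel from an individuals x SNPs dosage array."""
    dosages = np.asarray(dosages, float)
    n_snps = dosages.shape[1]
    if snp_ids is None:
        snp_ids = [f"rs{i}" for i in range(n_snps)]
    if chrom is None:
        chrom = ["1"] * n_snps
    if pos is None:
        pos = (np.arange(n_snps) + 1) * 1000
    return cf.ReferencePanel(np.asarray(snp_ids), np.asarray(chrom),
                             np.asarray(pos), dosages, haplotypes=haplotypes)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset shared across tests (panel-backed)."""
    spec = cf.ArchitectureSpec(n_snps=4000, n_chromosomes=4, seed=7,
                               apoe_like=cf.ApoeLikeSpec(chrom="4", n_snps=60))
    panel = cf.simulate_panel(spec, 200, store_haplotypes=True)
    a, b, truth = cf.simulate_sumstats(spec, panel)
    merged = cf.merge_traits(a, b)
    return {"spec": spec, "panel": panel, "a": a, "b": b, "truth": truth,
            "merged": merged}


@pytest.fixture
def table1(data_dir):
    return pd.read_csv(data_dir / "load_given_mdd_loci.tsv", sep="\t",
                       dtype={"chrom": str})


@pytest.fixture
def table2(data_dir):
    return pd.read_csv(data_dir / "mdd_given_load_loci.tsv", sep="\t",
                       dtype={"chrom": str})
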