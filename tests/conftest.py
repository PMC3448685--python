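import numpy as np
import pandas as pd
import pytest

from mirqtl.datamodel import CovariateTable, ExpressionMatrix, GenotypeMatrix, SnpRecord


def make_genotypes(columns: dict, sample_prefix: str = "S", snps: dict | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {snp_id: dosage list}."""
    n = len(next(iter(columns.values())))
    idx = pd.Index([f"{sample_prefix}{i}" for i in range(n)], name="sample_id")
    df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()}, index=idx)
    return GenotypeMatrix(df, snps or {})


def make_expression(columns: dict, sample_prefix: str = "S") -> ExpressionMatrix:
    n = len(next(iter(columns.values())))
    idx = pd.Index([f"{sample_prefix}{i}" for i in range(n)], name="sample_id")
    return ExpressionMatrix(pd.DataFrame(columns, index=idx))


def make_covariates(n: int, rng: np.random.Generator, status: bool = False,
                    sample_prefix: str = "S") -> CovariateTable:
    idx = pd.Index([f"{sample_prefix}{i}" for i in range(n)], name="sample_id")
    data = {
        "age": rng.uniform(35, 74, n),
        "sex": rng.integers(0, 2, n).astype(float),
    }
    if status:
        data["status"] = rng.integers(0, 2, n).astype(float)
    return CovariateTable(pd.DataFrame(data, index=idx))


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_917)


def snp_record(snp_id="rs1", chrom="1", pos=999, **kw) -> SnpRecord:
    return SnpRecord(snp_id=snp_id, chrom=chrom, pos=pos, **kw)
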