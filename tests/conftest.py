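import numpy as np
import pandas as pd
import pytest

from burstlnc.containers import AllelicCountSet, GeneTable, TwoStateKinetics


@pytest.fixture
def small_counts() -> AllelicCountSet:
    genes = ["g1", "g2", "g3"]
    cells = ["c1", "c2"]
    totals = pd.DataFrame([[10, 0], [7, 3], [0, 5]], index=genes, columns=cells)
    cast = pd.DataFrame([[6, 0], [1, 0], [0, 2]], index=genes, columns=cells)
    c57 = pd.DataFrame([[4, 0], [1, 3], [0, 3]], index=genes, columns=cells)
    return AllelicCountSet(totals=totals, cast_reads=cast, c57_reads=c57)


@pytest.fixture
def gene_table() -> GeneTable:
    return GeneTable(pd.DataFrame({
        "gene_id": ["g1", "g2", "g3", "gX"],
        "chrom": ["chr1", "chr1", "chr2", "chrX"],
        "start": [1000, 2000, 5000, 100],
        "end": [1500, 3000, 9000, 900],
        "strand": ["+", "-", "+", "+"],
        "biotype": ["protein_coding", "lncRNA", "protein_coding", "protein_coding"],
        "imprinted": [False, False, False, False],
        "x_linked": [False, False, False, True],
    }))


@pytest.fixture
def reference_kinetics() -> TwoStateKinetics:
    return TwoStateKinetics(k_on=1.0, k_off=10.0, k_syn=60.0)


def beta_poisson_pmf_oracle(x, k_on, k_off, k_syn):
    """Independent fine numerical integration of the Beta-Poisson pmf.

    Adaptive QUADPACK integration: the algebraic-weight rule when a Beta
    shape is below one (singular endpoint), peak-bracketed plain quadrature
    otherwise.
    """
    import warnings

    from scipy.integrate import quad
    from scipy.special import betaln
    from scipy.stats import beta as beta_dist, poisson

    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for xi in np.atleast_1d(x):
            if k_on < 1.0 or k_off < 1.0:
                f = lambda p: poisson.pmf(xi, k_syn * p)
                v, _ = quad(f, 0, 1, weight="alg",
                            wvar=(k_on - 1.0, k_off - 1.0),
                            epsabs=1e-14, epsrel=1e-13, limit=500)
                v /= np.exp(betaln(k_on, k_off))
            else:
                pts = np.clip(
                    [beta_dist.ppf(q, k_on, k_off)
                     for q in (1e-10, 0.01, 0.5, 0.99, 1 - 1e-10)],
                    1e-12, 1 - 1e-12,
                )
                f = lambda p: np.exp(
                    poisson.logpmf(xi, k_syn * p)
                    + beta_dist.logpdf(p, k_on, k_off)
                )
                v, _ = quad(f, 0, 1, epsabs=1e-14, epsrel=1e-13, limit=500,
                            points=list(pts))
            out.append(v)
    return np.asarray(out)
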