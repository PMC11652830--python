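import numpy as np
import pytest

from mrmediate.sumstats import HarmonisedSet, SummaryDataset, VariantAssociation
from mrmediate.simulate import write_fixture_suite


def make_hset(bx, by, sy, sx=None, ids=None, outcome="outcome", exposure="exposure"):
    """Single-exposure HarmonisedSet from plain arrays (tests' workhorse)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    if sx is None:
        sx = np.full_like(bx, 1e-6)
    else:
        sx = np.asarray(sx, dtype=float)
    n = len(bx)
    if ids is None:
        ids = [f"rs{i+1}" for i in range(n)]
    return HarmonisedSet(
        exposure_labels=[exposure],
        outcome_label=outcome,
        variant_ids=list(ids),
        bx=bx.reshape(n, 1),
        sx=sx.reshape(n, 1),
        by=by,
        sy=sy,
        effect_alleles=["A"] * n,
        other_alleles=["G"] * n,
    )


def make_dataset(rows, label="trait"):
    """SummaryDataset from dicts with VariantAssociation defaults filled in."""
    ds = SummaryDataset(trait_label=label)
    for row in rows:
        base = dict(effect_allele="A", other_allele="G", beta=0.1, se=0.01,
                    pval=1e-10)
        base.update(row)
        ds.add(VariantAssociation(**base))
    return ds


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The canonical named fixture files, written once per session."""
    d = tmp_path_factory.mktemp("fixtures")
    return write_fixture_suite(d)
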