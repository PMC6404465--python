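import numpy as np
import pytest

from ivmr.data import HarmonizedInstrumentSet, SummaryAssociation


def build_hset(beta_x, se_x, beta_y, se_y, rsids=None, eaf=None, scale=1.0):
    """Assemble an already-harmonized instrument set from raw arrays."""
    beta_x = np.asarray(beta_x, dtype=float)
    se_x = np.asarray(se_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    j = beta_x.size
    rsids = rsids or [f"rs{i}" for i in range(j)]
    eaf = eaf if eaf is not None else [0.3] * j
    records = []
    for i in range(j):
        exp = SummaryAssociation(rsid=rsids[i], effect_allele="A",
                                 other_allele="G", beta=float(beta_x[i]),
                                 se=float(se_x[i]), eaf=float(eaf[i]))
        out = SummaryAssociation(rsid=rsids[i], effect_allele="A",
                                 other_allele="G", beta=float(beta_y[i]),
                                 se=float(se_y[i]), eaf=float(eaf[i]))
        records.append((exp, out))
    return HarmonizedInstrumentSet(records=tuple(records),
                                   exposure_scale=scale)


def hset_from_ratios(theta, se, beta_x=None):
    """Instrument set whose Wald ratios/SEs are exactly (theta, se)."""
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    bx = np.ones_like(theta) if beta_x is None else np.asarray(beta_x, float)
    return build_hset(bx, np.full_like(theta, 1e-6), theta * bx, se * np.abs(bx))


@pytest.fixture
def make_hset():
    return build_hset


@pytest.fixture
def make_ratio_hset():
    return hset_from_ratios


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name, header, rows, sep="\t"):
        path = tmp_path / name
        lines = [sep.join(header)]
        lines += [sep.join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path
    return _write
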