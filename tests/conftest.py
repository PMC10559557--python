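import numpy as np
import pytest

from svforge import SampleInfo, SimConfig, simulate_truth
from svforge.types import GenotypeMatrix, MergedLocus, SVRecord


def make_record(chrom="chr1", start=1000, end=1500, svtype="DEL", qual=300.0,
                filt="PASS", caller="callerA", sample="s1", mei_family="none",
                mei_length=300):
    if svtype == "MEI":
        return SVRecord(chrom, start, start, "MEI", mei_length, qual, filt,
                        ".", mei_family if mei_family != "none" else "SINE",
                        caller, sample)
    return SVRecord(chrom, start, end, svtype, end - start + 1, qual, filt,
                    ".", "none", caller, sample)


def make_locus(locus_id="L0", chrom="chr1", start=1000, end=1500,
               svtype="DEL", **kw):
    return MergedLocus.from_members(
        locus_id, [make_record(chrom, start, end, svtype, **kw)])


def make_gm(dosages, sample_prefix="s", breed=None, loci=None):
    dosages = np.asarray(dosages, dtype=float)
    n_loci, n_samples = dosages.shape
    if loci is None:
        loci = [make_locus(f"L{i}", start=1000 + 10_000 * i,
                           end=1400 + 10_000 * i) for i in range(n_loci)]
    samples = []
    for j in range(n_samples):
        b = breed[j] if breed is not None else "pop"
        samples.append(SampleInfo(f"{sample_prefix}{j}", b, "F0"))
    return GenotypeMatrix(loci, samples, dosages)


@pytest.fixture(scope="session")
def tiny_truth():
    """A small deterministic synthetic study truth shared across tests."""
    cfg = SimConfig.small(7)
    return simulate_truth(cfg), cfg
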