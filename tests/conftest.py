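import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fhscreen.simulate import SimulationParams, simulate_cohort, write_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_participants=1200, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_params):
    return simulate_cohort(small_params)


@pytest.fixture(scope="session")
def cohort_manifest(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    return write_cohort(small_bundle, out)


@pytest.fixture()
def vcf_writer(tmp_path):
    """Write a minimal GT-only VCF; records are (chrom, pos, id, ref, alt, gts)."""

    def _write(samples, records, name="test.vcf"):
        path = tmp_path / name
        chroms = []
        for r in records:
            if r[0] not in chroms:
                chroms.append(r[0])
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            for chrom, pos, vid, ref, alt, gts in records:
                fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts) + "\n")
        return path

    return _write


def central_binomial_interval(n: int, p: float, mass: float = 0.99):
    """Central interval of Bin(n, p) by direct pmf summation (oracle)."""
    from math import comb

    pmf = np.array([comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)])
    cdf = np.cumsum(pmf)
    tail = (1 - mass) / 2
    lo = int(np.searchsorted(cdf, tail))
    hi = int(np.searchsorted(cdf, 1 - tail))
    return lo, hi
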