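import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

import polyscan as ps


@pytest.fixture
def toy_vcf(tmp_path):
    """Mixed-ploidy VCF: 4 samples (2 diploid, 2 tetraploid), 5 sites."""
    text = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=10000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\td1\td2\tt1\tt2
chr1\t100\t.\tA\tT\t.\t.\t.\tGT:DP\t0/0:30\t0/1:30\t0/1/1/1:30\t1/1/1/1:30
chr1\t200\t.\tG\tC\t.\t.\t.\tGT:DP\t0/1:30\t./.:30\t0/0/0/1:30\t0/0/0/0:30
chr1\t300\t.\tT\tA\t.\t.\t.\tGT:DP\t0/0:2\t0/1:30\t0/0/1/1:30\t0/0/0/0:30
chr1\t400\t.\tC\tG\t.\t.\t.\tGT:DP\t./.:30\t./.:30\t0/1/1/1:30\t1/1/1/1:30
chr1\t500\t.\tA\tC\t.\t.\t.\tGT:DP\t1/1:30\t1/1:30\t0/0/0/0:30\t0/0/0/0:30
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return str(path)


@pytest.fixture
def toy_popmap(tmp_path):
    text = (
        "d1\tLDA\tlyrata2x\n"
        "d2\tLDA\tlyrata2x\n"
        "t1\tLTA\tlyrata4x\n"
        "t2\tLTA\tlyrata4x\n"
    )
    path = tmp_path / "popmap.tsv"
    path.write_text(text)
    return str(path)


@pytest.fixture(scope="session")
def shallow_scenario():
    """Shallow splits + large Ne: heavy incomplete sorting, phase-sensitive
    weightings."""
    return ps.DemographyScenario(
        seed=3,
        migration=0.0,
        split_gen=60_000,
        wgd_lyrata_gen=20_000,
        wgd_arenosa_gen=30_000,
        outgroup_split_gen=200_000,
        ne={t: 50_000.0 for t in ps.simulate.TAXON_PLOIDY},
        ancestral_ne=50_000.0,
        seq_len=1_200,
    )


@pytest.fixture(scope="session")
def deep_dataset():
    """Default deep-split dataset with two sweeps and two pulses (session-
    scoped; several tests read it)."""
    scenario = ps.DemographyScenario(seed=11, migration=0.0)
    pulse_a = ps.IntrogressionPulse("arenosa4x", "lyrata4x", time=5_000, fraction=1.0)
    pulse_b = ps.IntrogressionPulse("lyrata4x", "arenosa4x", time=5_000, fraction=1.0)
    gm, pm, windows, truth = ps.generate_dataset(
        scenario,
        40,
        sweep_spec={7: ("lyrata4x", 1.0)},
        introgression_spec={15: pulse_a, 28: pulse_b},
    )
    return scenario, gm, pm, windows, truth
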