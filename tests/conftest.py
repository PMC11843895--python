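import pytest

import g4methyl as gm


@pytest.fixture(scope="session")
def amplicon():
    return gm.study_sequence("MGMT-752")


@pytest.fixture(scope="session")
def cpg_index(amplicon):
    return gm.find_cpg_sites(amplicon)


@pytest.fixture(scope="session")
def range_labels(cpg_index):
    """Site labels for the default primary PQS region (site numbers 47-72)."""
    return {
        pos: ("PQS" if 47 <= num <= 72 else "non-PQS")
        for pos, num in zip(cpg_index.positions, cpg_index.site_numbers)
    }


@pytest.fixture(scope="session")
def pqs_overlap_labels(amplicon, cpg_index):
    """Site labels derived from called PQS intervals on the amplicon."""
    track = gm.g4hunter_scores(amplicon)
    intervals = gm.call_pqs(track)
    return gm.pqs_cpg_overlap(intervals, cpg_index, len(amplicon))


@pytest.fixture(scope="session")
def dnmt3a_pileup(amplicon, cpg_index, range_labels):
    """One dnmt3a-preset simulation at the default depth, shared across tests."""
    truth, noise = gm.preset_truth("dnmt3a")
    reads = gm.simulate_reads(
        amplicon, cpg_index, range_labels, truth, noise, 500, seed=1
    )
    return gm.pileup(reads, cpg_index, 0.65, amplicon.id)
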