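import pytest

from globinscan import datasets


@pytest.fixture(scope="session")
def globins():
    return datasets.load_globins()


@pytest.fixture(scope="session")
def band3():
    return datasets.load_band3_synthetic()


@pytest.fixture(scope="session")
def cavity_sets():
    return datasets.load_cavity_sets()


@pytest.fixture(scope="session")
def topology_regions():
    return datasets.load_topology_regions()


@pytest.fixture(scope="session")
def published_motifs():
    return datasets.load_published_motifs()


# ---------------------------------------------------------------------
# Independent brute-force motif oracle: checks every candidate triple /
# window directly against the written pattern definitions, with no code
# shared with the pattern engine.
# ---------------------------------------------------------------------

def brute_force_cholesterol(seq: str, kind: str):
    """All (start, central, end) 1-based triples satisfying the CRAC or
    CARC definition, by direct inspection of every candidate."""
    first, central_set, last = {
        "CRAC": ("LV", "Y", "KR"),
        "CARC": ("KR", "YF", "LV"),
    }[kind]
    n = len(seq)
    out = []
    for i in range(1, n + 1):
        if seq[i - 1] not in first:
            continue
        for c in range(i + 2, min(i + 6, n) + 1):
            if seq[c - 1] not in central_set:
                continue
            for j in range(c + 2, min(c + 6, n) + 1):
                if seq[j - 1] in last:
                    out.append((i, c, j))
    return sorted(out)


CAV_OFFSETS = {"CAV_8B": (0, 2, 7), "CAV_8A": (0, 5, 8), "CAV_11": (0, 2, 7, 10)}


def brute_force_caveolin(seq: str, kind: str):
    """All (start, end) windows satisfying a caveolin variant."""
    offs = CAV_OFFSETS[kind]
    length = offs[-1] + 1
    out = []
    for i in range(1, len(seq) - length + 2):
        if all(seq[i - 1 + o] in "WYF" for o in offs):
            out.append((i, i + length - 1))
    return out
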