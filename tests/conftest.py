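import numpy as np
import pytest

from hisol import (
    AMINO_ACIDS,
    AlignmentProfile,
    MultipleAlignment,
    kyte_doolittle_scale,
)

# Three aligned homolog sequences used across the format/parsing tests.
SMALL_RECORDS = [
    ("seq1", "MKIL-VAQWE"),
    ("seq2", "MKIV-VAQWD"),
    ("seq3", "MRIL-VSQWE"),
]


@pytest.fixture(scope="session")
def scale():
    return kyte_doolittle_scale("population")


@pytest.fixture
def small_fasta(tmp_path):
    path = tmp_path / "small.fasta"
    path.write_text("".join(f">{rid}\n{seq}\n" for rid, seq in SMALL_RECORDS))
    return path


@pytest.fixture
def small_clustal(tmp_path):
    path = tmp_path / "small.aln"
    body = "\n".join(f"{rid:<10}{seq}" for rid, seq in SMALL_RECORDS)
    path.write_text(f"CLUSTAL W (1.82) multiple sequence alignment\n\n{body}\n")
    return path


@pytest.fixture
def small_stockholm(tmp_path):
    path = tmp_path / "small.sto"
    body = "\n".join(f"{rid:<10}{seq}" for rid, seq in SMALL_RECORDS)
    path.write_text(f"# STOCKHOLM 1.0\n{body}\n//\n")
    return path


def profile_from_rates(target_sequence: str, rates: dict[int, dict[str, float]],
                       coverage: int = 100) -> AlignmentProfile:
    """Build a profile directly from per-position rate dictionaries.

    Positions not listed get a column 100% conserved as the target
    residue.  Intended for exact-score tests where column composition,
    not sampling, is the input.
    """
    L = len(target_sequence)
    comp = np.zeros((L, 20))
    aa_pos = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for j in range(L):
        row = rates.get(j + 1, {target_sequence[j]: 100.0})
        for aa, rate in row.items():
            comp[j, aa_pos[aa]] = rate
    cov = np.full(L, coverage, dtype=np.int64)
    counts = np.rint(comp * coverage / 100.0).astype(np.int64)
    return AlignmentProfile(
        target_id="target",
        target_sequence=target_sequence,
        column_of_position=np.arange(1, L + 1),
        composition=comp,
        counts=counts,
        coverage=cov,
        n_sequences=coverage + 1,
    )
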