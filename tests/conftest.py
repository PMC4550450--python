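from __future__ import annotations

import numpy as np
import pytest

from coiaaevol.dayhoff import AMINO_ACIDS, load_dayhoff_model
from coiaaevol.simulate import OrderSpec, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def model():
    return load_dayhoff_model()


@pytest.fixture(scope="session")
def clean_sim():
    """Two-order dataset with no indels and no corruption."""
    cfg = SimConfig(seed=101, orders=(
        OrderSpec("Alphida", n_families=3, bins_per_family=(2, 3)),
        OrderSpec("Betida", n_families=3, bins_per_family=(2, 3),
                  rate_multiplier=2.0),
    ))
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def indel_sim():
    """Two-order dataset with injected deletions and NUMT contaminants."""
    cfg = SimConfig(seed=202, orders=(
        OrderSpec("Alphida", n_families=4, bins_per_family=(2, 4),
                  indel_rate=0.004),
        OrderSpec("Betida", n_families=4, bins_per_family=(2, 4),
                  indel_rate=0.004),
    ), numt_fraction=0.1, ambiguous_base_rate=0.001)
    return simulate_dataset(cfg)


def random_protein(rng: np.random.Generator, n: int, pi=None) -> str:
    if pi is None:
        model = load_dayhoff_model()
        pi = model.equilibrium_freqs
    return "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=n, p=pi))


def evolve_protein(protein: str, t: float, model,
                   rng: np.random.Generator) -> str:
    """Site-wise CTMC evolution of a protein string (test oracle helper)."""
    P = model.transition_matrix(t)
    idx = np.array([AMINO_ACIDS.index(a) for a in protein])
    out = [AMINO_ACIDS[rng.choice(20, p=P[i])] for i in idx]
    return "".join(out)


def write_dataset_files(tmp_path, records):
    """Write records to FASTA + metadata TSV; returns (fasta, meta) paths."""
    fasta = tmp_path / "seqs.fasta"
    meta = tmp_path / "meta.tsv"
    with open(fasta, "w") as fh:
        for r in records:
            fh.write(f">{r.record_id}\n{r.nt_seq}\n")
    with open(meta, "w") as fh:
        fh.write("record_id\tbin_id\torder\tfamily\tgenus\tsource\n")
        for r in records:
            fh.write(f"{r.record_id}\t{r.bin_id}\t{r.order}\t{r.family}\t"
                     f"{r.genus}\t{r.source}\n")
    return fasta, meta
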