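"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from phycodelim import FoldParams, Its2FamilySpec, write_fasta

HELIX_REGIONS = ("helix I", "helix II", "helix III", "helix IV")


def random_change_map(rng: np.random.Generator) -> dict:
    """A feasible random planted-change request.

    CBC and hCBC requests go to different helices so the separation rules
    of the generator always leave enough eligible sites.
    """
    order = rng.permutation(4)
    cm: dict = {}
    if rng.random() < 0.7:
        cm.setdefault("CBC", {})[HELIX_REGIONS[order[0]]] = int(rng.integers(1, 3))
    if rng.random() < 0.6:
        cm.setdefault("hCBC", {})[HELIX_REGIONS[order[1]]] = 1
    if rng.random() < 0.6:
        cm.setdefault("substitution", {})["spacer"] = int(rng.integers(1, 3))
    if rng.random() < 0.5:
        cm.setdefault("indel", {})["spacer"] = 1
    return cm


def family_spec(seed: int, change_map: dict | None = None) -> Its2FamilySpec:
    if change_map is None:
        change_map = random_change_map(np.random.default_rng(seed + 10_000))
    return Its2FamilySpec(seed=seed, n_variants=1, planted_changes=(change_map,))


@pytest.fixture
def unconstrained_params() -> FoldParams:
    return FoldParams(require_motifs=False)


@pytest.fixture
def fasta_writer(tmp_path):
    """Write records (or raw text) to a temporary FASTA file."""

    def write(records_or_text, name="input.fasta"):
        path = tmp_path / name
        if isinstance(records_or_text, str):
            path.write_text(records_or_text)
        else:
            write_fasta(records_or_text, path)
        return path

    return write
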