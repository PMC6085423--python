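import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ribovar.simulate import (
    SimConfig,
    simulate_clone_reads,
    simulate_repeat_array,
    simulate_sanger_reference,
)


@pytest.fixture(scope="session")
def default_run():
    """One default-condition simulated run shared across tests."""
    cfg = SimConfig(seed=1)
    sim = simulate_repeat_array(cfg)
    reference, secondary = simulate_sanger_reference(sim)
    clones = simulate_clone_reads(sim, cfg)
    return cfg, sim, reference, secondary, clones


@pytest.fixture(scope="session")
def small_sim_dir(tmp_path_factory):
    """A small simulated input directory for pipeline tests."""
    from ribovar.pipeline import run_simulate

    out = tmp_path_factory.mktemp("sim") / "run"
    cfg = SimConfig(seed=11, n_clones=16, n_copies=30, read_error_rate=0.003)
    run_simulate(cfg, out)
    return out


# ---------------------------------------------------------------------------
# independent oracles

def affine_score(aligned_a: str, aligned_b: str, match, mismatch, gap_open, gap_extend):
    """Score a gapped alignment directly from its columns."""
    score = 0.0
    for seq in (aligned_a, aligned_b):
        in_gap = False
        for c in seq:
            if c == "-":
                score += gap_extend if in_gap else gap_open
                in_gap = True
            else:
                in_gap = False
    for x, y in zip(aligned_a, aligned_b):
        if x != "-" and y != "-":
            score += match if x == y else mismatch
    return score


def enumerate_alignments(a: str, b: str):
    """Every global alignment of two short strings (exponential; <= 8 bp)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def best_alignment_score(a, b, match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0):
    return max(
        affine_score(ra, rb, match, mismatch, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )
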