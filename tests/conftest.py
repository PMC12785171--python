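"""Shared fixtures: small simulated scenarios every suite can reuse."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import HealthCheck, settings

from telocap.simulate import SimConfig, TruthTable, make_alignments, make_genome, simulate_reads
from telocap.seqio import AlnRecord, SeqRecord

settings.register_profile(
    "telocap",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("telocap")


@dataclass
class Scenario:
    config: SimConfig
    truth_genome: list[SeqRecord]
    truncated_genome: list[SeqRecord]
    truth: TruthTable
    reads: list[SeqRecord]
    alignments: list[AlnRecord]

    @property
    def lookup(self) -> dict[str, str]:
        return {r.id: r.sequence for r in self.reads}


def build_scenario(config: SimConfig) -> Scenario:
    truth_genome, truncated, truth = make_genome(config)
    reads = simulate_reads(truth_genome, config, truth)
    alignments = make_alignments(reads, truncated, truth)
    return Scenario(config, truth_genome, truncated, truth, reads, alignments)


SMALL_CONFIG = SimConfig(
    n_chroms=2,
    chrom_len_bp=30_000,
    telo_len_bp=1000,
    truncate_bp={("chr1", "R"): 800, ("chr2", "L"): 600},
    read_len_mean=4000,
    read_len_sd=600,
    depth=15.0,
    seed=11,
)

# min_run_bp used with the small scenario: remnants are 200 bp (chr1 R) and
# 400 bp (chr2 L), so both truncated ends are flagged while intact 1-kb
# arrays are not
SMALL_MIN_RUN = 500


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    """Error-free 2x30-kb scenario with one R and one L truncation."""
    return build_scenario(SMALL_CONFIG)


@pytest.fixture(scope="session")
def noisy_scenario() -> Scenario:
    """Same scenario with 2% substitutions and 0.5% indels."""
    cfg = SimConfig(
        n_chroms=2,
        chrom_len_bp=30_000,
        telo_len_bp=1000,
        truncate_bp={("chr1", "R"): 800, ("chr2", "L"): 600},
        read_len_mean=4000,
        read_len_sd=600,
        depth=15.0,
        sub_rate=0.02,
        ins_rate=0.0025,
        del_rate=0.0025,
        seed=11,
    )
    return build_scenario(cfg)
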