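"""Shared fixtures: a published two-breed candidate-region table used for
internal-consistency checks, a hand-audited filter table, and small
simulated datasets."""

import numpy as np
import pandas as pd
import pytest

import poolsweep as ps

# Candidate selective-sweep windows from a published Shiba Inu vs Mame
# Shiba Inu pool-seq scan (12 windows in the top 1% of F_ST, -ZHp and
# normalized XP-CLR simultaneously), with the printed genome-wide top-1%
# thresholds.  Used to validate the Z-transform arithmetic and the
# intersection/summary logic against independently produced numbers.
CANDIDATE_TABLE = pd.DataFrame(
    [
        ("1", 109_625_000, 109_650_000, 0.149, 0.076, 2.873, 3.305, ["CCDC61"]),
        ("1", 116_300_000, 116_325_000, 0.149, 0.040, 3.292, 6.477, ["ZNF382", "ZNF461"]),
        ("3", 52_950_000, 52_975_000, 0.196, 0.008, 3.677, 15.727, []),
        ("5", 40_575_000, 40_600_000, 0.199, 0.045, 3.232, 3.143, ["ALDH3A2"]),
        ("5", 42_875_000, 42_900_000, 0.184, 0.060, 3.060, 9.002, ["ENSCAFG00000018533"]),
        ("5", 57_800_000, 57_825_000, 0.170, 0.031, 3.406, 8.475, ["PRDM16"]),
        ("5", 57_825_000, 57_850_000, 0.211, 0.040, 3.297, 20.152, ["PRDM16"]),
        ("8", 34_250_000, 34_275_000, 0.147, 0.044, 3.244, 24.152, ["ENSCAFG00000033351"]),
        ("8", 62_250_000, 62_275_000, 0.149, 0.064, 3.015, 4.824, []),
        ("27", 18_625_000, 18_650_000, 0.217, 0.041, 3.278, 19.421, ["ERGIC2"]),
        ("33", 23_675_000, 23_700_000, 0.169, 0.055, 3.121, 31.624, ["ENSCAFG00000011141"]),
        ("36", 7_975_000, 8_000_000, 0.162, 0.040, 3.294, 25.154, []),
    ],
    columns=["chrom", "start", "end", "fst", "hp", "zhp", "xpclr", "genes"],
)

#: genome-wide top-1% thresholds printed alongside the table
THRESHOLDS = {"fst": 0.146, "zhp": 2.860, "xpclr": 3.07}


@pytest.fixture
def candidate_table():
    return CANDIDATE_TABLE.copy()


def audit_table():
    """A 30-record table with hand-planted violations of every filter rule.

    Returns ``(records, expected_retained)``; the expected count was
    tallied by hand while placing each record:

    * 20 SNPs pass every rule (including three boundary cases: pooled
      MAF exactly 0.05, per-pool depth exactly 10, quality exactly 20,
      and two SNPs exactly 16 bp from an indel);
    * 8 SNPs each violate at least one rule (MAF 0.04, pool-1 depth 9,
      quality 19, four SNPs within 15 bp of an indel, pool-2 depth 8,
      one SNP violating MAF and quality at once);
    * 2 indel records act as exclusion anchors.
    """
    R = ps.VariantRecord
    ok = dict(qual=50.0, ref1=30, alt1=10, ref2=40, alt2=20)
    rows = [
        R("chr1", 100, "A", "G", **ok),                                  # pass
        R("chr1", 200, "A", "G", 50.0, 50, 3, 45, 2),                    # MAF = 5/100 = 0.05: pass
        R("chr1", 300, "A", "G", 50.0, 50, 2, 46, 2),                    # MAF 0.04: fail
        R("chr1", 400, "A", "G", 50.0, 5, 4, 20, 10),                    # pool1 depth 9: fail
        R("chr1", 500, "A", "G", 50.0, 6, 4, 20, 10),                    # depth exactly 10: pass
        R("chr1", 600, "A", "G", 19.0, 30, 10, 40, 20),                  # quality 19: fail
        R("chr1", 700, "A", "G", 20.0, 30, 10, 40, 20),                  # quality exactly 20: pass
        R("chr1", 984, "A", "G", **ok),                                  # 16 bp from indel: pass
        R("chr1", 985, "A", "G", **ok),                                  # 15 bp from indel: fail
        R("chr1", 1000, "AT", "A", 50.0, 20, 10, 20, 10),                # indel anchor
        R("chr1", 1015, "A", "G", **ok),                                 # 15 bp: fail
        R("chr1", 1016, "A", "G", **ok),                                 # 16 bp: pass
        R("chr1", 3000, "C", "T", **ok),                                 # pass
        R("chr1", 4990, "C", "T", **ok),                                 # 10 bp from indel: fail
        R("chr1", 5000, "G", "GA", 50.0, 20, 10, 20, 10),                # indel anchor
        R("chr1", 5016, "C", "T", **ok),                                 # pass
        R("chr2", 100, "G", "A", **ok),                                  # pass
        R("chr2", 200, "G", "A", 10.0, 49, 1, 49, 1),                    # MAF 0.02 + qual 10: fail
        R("chr2", 300, "G", "A", **ok),                                  # pass
        R("chr2", 400, "G", "A", 50.0, 30, 10, 4, 4),                    # pool2 depth 8: fail
    ] + [
        R("chr2", 500 + 100 * i, "T", "C", **ok) for i in range(10)      # 10 passes
    ]
    expected_retained = 20
    return ps.records_frame(rows), expected_retained


@pytest.fixture(scope="session")
def small_dataset():
    """One 2-Mb chromosome with a central sweep, filtered; used by tests
    that need realistic windowed data without full-study scale."""
    config = ps.SimulationConfig(seed=7, chrom_lengths=(2_000_000,))
    sweeps = [ps.SweepSpec("chr1", 1_000_000)]
    records, annotation, truth = ps.simulate_dataset(config, sweeps)
    retained, report = ps.apply_filters(records)
    return {
        "config": config, "sweeps": sweeps, "records": records,
        "annotation": annotation, "truth": truth, "retained": retained,
        "report": report,
    }
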