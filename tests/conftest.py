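import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import repquant as rq
from repquant.presets import oracle_config

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# RepeatMasker .out fixture: 6 records, 2 of class Simple_repeat
RM_OUT_TEXT = """\
   SW  perc perc perc  query      position in query    matching repeat              position in  repeat
score  div. del. ins.  sequence    begin     end    (left)    repeat         class/family         begin  end (left)   ID

  463   1.3  0.6  1.7  chr1         1001    1200  (19800) +  L1PA2          LINE/L1                 1   200    (0)      1
  239  29.4  1.9  1.0  chr1         2001    2300  (18700) C  AluY           SINE/Alu                 1   300    (0)      2
  318  23.0  3.7  0.0  chr1         3501    3800  (17200) +  L1PA3          LINE/L1                 1   300    (0)      3
   12   0.0  0.0  0.0  chr1         5001    5050  (15950) +  (TA)n          Simple_repeat            1    50    (0)      4
   13   2.0  0.0  0.0  chr2          501     560   (9440) C  (CAG)n         Simple_repeat            1    60    (0)      5
  202  15.3  0.5  0.0  chr2         1001    1400   (8600) +  MER4A          LTR/ERV1                 1   400    (0)      6
"""


@pytest.fixture(scope="session")
def rm_out_file(tmp_path_factory):
    p = tmp_path_factory.mktemp("ann") / "repeats.out"
    p.write_text(RM_OUT_TEXT)
    return p


@pytest.fixture(scope="session")
def oracle_toy():
    """Small toy landscape: two ~90%-identical LINE subfamilies plus an
    independent DNA-class subfamily, on a 30 kb contig."""
    return rq.make_toy_genome(oracle_config(1))


@pytest.fixture(scope="session")
def oracle_reads(oracle_toy):
    """Deterministic 30 bp reads drawn uniformly from the toy contig."""
    rng = np.random.default_rng(7)
    g = oracle_toy.genome["chrT"]
    reads = []
    for i in range(600):
        s = int(rng.integers(0, len(g) - 30))
        seq = g[s : s + 30]
        if rng.random() < 0.5:
            seq = rq.revcomp(seq)
        reads.append((f"r{i}", 0, seq))
    return reads
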