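"""Parse a repeat annotation and build per-subfamily pseudogenomes.

Generates a small synthetic genome with planted repeat copies, writes
its annotation in RepeatMasker .out layout, parses it back, filters
simple-sequence repeats, and builds the pseudogenome for each
subfamily (copies + 15 bp flanks joined by 200 bp N spacers).
"""

import tempfile
from pathlib import Path

import repquant as rq
from repquant.presets import oracle_config

tmp = Path(tempfile.mkdtemp())
toy = rq.make_toy_genome(oracle_config(seed=1))
toy.write_genome(tmp / "genome.fa")
toy.write_repeatmasker(tmp / "repeats.out")

instances, hierarchy = rq.parse_repeatmasker(tmp / "repeats.out")
instances = rq.filter_repeat_classes(instances)  # drops Simple_repeat
print(f"parsed {len(instances)} repeat instances, "
      f"{len(hierarchy)} subfamilies: {hierarchy.subfamilies}")

pgs = rq.build_pseudogenome_set(instances, toy.genome)
for sub, pg in pgs.items():
    n = len(pg.offsets)
    print(f"  {sub}: {n} copies -> pseudogenome of {len(pg)} bp "
          f"({n - 1} spacer(s) of 200 bp)")
# Each pseudogenome concatenates every genomic copy of one subfamily;
# multi-mapping reads are aligned against these instead of the genome.
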