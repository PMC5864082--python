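"""Simulate a pooled competition, emit barcode reads, and count them.

Builds a 60-strain barcoded pool, grows it from the initial pool (P)
through batch (B) into steady state, sequences the UPTAG/DOWNTAG libraries
of the pool-stage sample, and tallies reads back to strains under the
full-length ≤1-mismatch rule.
"""

import tempfile
from pathlib import Path

from barfit.sim import SimConfig, emit_reads, make_catalog, make_sample_sheet, \
    simulate_pool, write_fastq
from barfit.tagcount import count_run

cfg = SimConfig(n_strains=60, depth=3000, error_rate=0.005, seed=1)
catalog = make_catalog(cfg.n_strains, seed=cfg.seed)
sheet = make_sample_sheet(("Clim30",), n_bio_reps=cfg.n_bio_reps)

states, truth = simulate_pool(cfg, "Clim30")
sample = sheet.rows[0]  # pool stage, repeat 1
up, down, draws = emit_reads(states[0], catalog, sample, cfg)

with tempfile.TemporaryDirectory() as td:
    paths = [Path(td) / "up.fastq", Path(td) / "down.fastq"]
    write_fastq(up, paths[0])
    write_fastq(down, paths[1])
    cm = count_run(paths, catalog, sheet)

acc = cm.accounting.loc[sample.sample_id]
print(f"reads processed : {acc['reads']}")
print(f"TAG hits        : {acc['hits']}  "
      f"({100 * acc['hits'] / acc['reads']:.1f}% identified)")
print(f"no TAG found    : {acc['no_tag']}  (flank destroyed by read errors)")
print(f"unmatched       : {acc['unmatched']}  (>1 mismatch to every TAG)")
print(f"top strain count: {cm.counts[sample.sample_id].max()} "
      f"(expected ≈ 2·depth/n = {2 * cfg.depth // cfg.n_strains})")
# At 0.5% per-base error most reads still identify their TAG; reads whose
# flank or TAG picked up >1 substitution land in the no_tag/unmatched bins.
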