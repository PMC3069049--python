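"""Flag fragmentary or mispredicted sequences with the four empirical
rules: terminal errors (quartile window on terminal positions), outlier
segments (low profile score in a core block), inserted segments
(single-sequence runs between full columns) and deleted segments
(single-sequence gap runs).
"""

from alnbench import BlockSpec, FamilySpec, filter_reliable, generate, scan
from alnbench.synthetic import plant_discrepancy

truth = generate(FamilySpec(
    subfamily_sizes=(8,),
    blocks=tuple(BlockSpec(24, (0,), 0.9) for _ in range(4)),
    seed=3,
    linker_length=12,
    linker_jitter=2,
))
ids = truth.alignment.ids
hosts = [b.block_id for b in truth.blocks]
truth = plant_discrepancy(truth, "outlier_segment", 0, seed=1,
                          target_id=ids[0], block_id=hosts[0])
truth = plant_discrepancy(truth, "inserted_segment", 12, seed=2,
                          target_id=ids[1], block_id=hosts[1])
truth = plant_discrepancy(truth, "deleted_segment", 12, seed=3,
                          target_id=ids[2], block_id=hosts[2])
truth = plant_discrepancy(truth, "terminal_error", 25, seed=4,
                          target_id=ids[3])

report = scan(truth.alignment, subfamilies=truth.subfamilies)
print("flags:")
for d in report.discrepancies:
    side = f" ({d.terminal_side}-terminal)" if d.terminal_side else ""
    print(f"  {d.seq_id}: {d.kind}{side}, columns {d.start + 1}-{d.stop}")
print(f"reliable sequences: {len(report.reliable_ids)} of {truth.alignment.n_seqs}")

filtered, _ = filter_reliable(truth.alignment, report, truth.blocks)
print(f"filtered alignment: {filtered.n_seqs} x {filtered.n_cols}")
# Each planted error is recovered on the right sequence with the right
# kind; the filtered alignment keeps only the sequences a benchmark
# would trust.
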