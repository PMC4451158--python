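"""Leave-one-out species identification by both barcoding methods.

Each sample in turn becomes the query against the remaining 73; a query
is correct when the nearest reference (by K2P distance) or the top local
alignment hit (BLAST1-style) belongs to its own species.
"""

from its2barcode import Method, leave_one_out_eval, progressive_msa
from its2barcode.simulate import SimulationConfig, simulate_dataset

records, _ = simulate_dataset(SimulationConfig(seed=1))
msa = progressive_msa(records)

for method in (Method.NEAREST_DISTANCE, Method.BLAST1):
    report = leave_one_out_eval(records, method, msa=msa)
    print(f"{method.value}: {report.n_correct}/{report.n_queries} correct "
          f"= {report.success_rate:.1f}%")
    worst = min(report.results, key=lambda r: r.margin)
    print(f"  tightest call: {worst.query_id} "
          f"(margin to runner-up species {worst.margin:.4g})")

# With zero intraspecific variation and positive interspecific distance a
# 100% success rate is guaranteed for nearest-distance; the BLAST1-style
# method agrees because local alignment score ranks references the same
# way on well-separated barcodes.
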