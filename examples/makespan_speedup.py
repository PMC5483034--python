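"""Quantify why chunks are balanced by length, not record count.

Simulates an idealized cluster where task time is proportional to chunk
residue length, on a longest-first sorted input (the order de novo
assemblers emit transcripts). Count-balanced splitting piles the longest
transcripts into the first chunk; length-balanced splitting keeps every
worker busy, so its speed-up stays near the worker count.
"""

from dcsearch import CostModel, simulate_makespan, synth_queryset

lengths = synth_queryset(1024, law=("descending", 5000, 4), seed=0).lengths
model = CostModel(cost_per_residue=1e-4, per_task_overhead=0.0)

print(f"{'workers':>8} {'length-balanced':>16} {'count-balanced':>15}")
for n in (1, 8, 16, 32, 64):
    lb = simulate_makespan(lengths, "length_balanced", n, model)
    cb = simulate_makespan(lengths, "count_balanced", n, model)
    print(f"{n:>8} {lb.speedup:>15.2f}x {cb.speedup:>14.2f}x")
print("speed-up = serial time / makespan; the ideal value equals the worker count")
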