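"""When does the surrogate pay off? The break-even replica count.

Reference workflow numbers: 20,000 training solves at 1.16 s each, 12 h of
training, and a surrogate that evaluates 1000x faster than the solver.
"""

from diffsurrogate import BreakevenInputs, n_min, parse_duration, workflow_times

inputs = BreakevenInputs(
    M=20_000,
    E=parse_duration("12h"),
    delta=1.16,
    epsilon=1.16 / 1000,
)
nm = n_min(inputs)
print(f"N_min = {nm:,.0f} surrogate evaluations to amortize data + training cost")

for N in (10_000, int(nm), 1_000_000):
    td, tn = workflow_times(inputs, N)
    winner = "direct" if td < tn else ("tie" if abs(td - tn) < 1 else "surrogate")
    print(f"  N = {N:>9,d}: direct {td / 3600:8.1f} h, "
          f"surrogate workflow {tn / 3600:8.1f} h  -> {winner}")
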