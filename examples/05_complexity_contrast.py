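"""Per-group network complexity: denser correlations, higher entropy.

Two equal groups share the same variables, but the 'control' group's
within-block correlations are denser than the 'case' group's.  Building
Auto-CM -> MST -> MRG separately per group, the control network re-gains
more of its removed links, raising the topological entropy E_G while the
hubness H barely moves — loss of correlation density reads as loss of
network complexity.
"""

from cohortnet import expand_indicators, generate_contrast_cohort, group_complexity_contrast

cohort = generate_contrast_cohort(n_per_group=150, case_corr=0.45, control_corr=0.85, seed=0)
matrix = expand_indicators(cohort)
gc = group_complexity_contrast(matrix.feature_frame(), cohort.outcome)

for name, rep in (("case", gc.case), ("control", gc.control)):
    print(f"{name:8s} H = {rep.H:.3f}  E_G = {rep.E_G:6.1f}  "
          f"arcs = {rep.A}  pruning cycles = {rep.P}")
print(f"\ndelta H   (control - case) = {gc.delta_H:+.3f}")
print(f"delta E_G (control - case) = {gc.delta_E_G:+.1f}")
print("\nPositive delta E_G with near-zero delta H: the complexity gap "
      "comes from the overall density of connections, not from new hubs.")
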