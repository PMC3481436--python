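"""Certify zero-input stability of the homeostatic origin.

Builds the saturated quadratic bound on the Lyapunov derivative, checks its
eigenvalues, prints the term-by-term slack of the hand completed-square
decomposition, and runs the random-state domination check. The last two
checks expose known defects of the hand derivation: the x3^2 budget of the
completed-square form is overdrawn, and saturating the Hill factor inside
the stabilizing -k_i*h*x1^2 terms is not a true upper bound.
"""

import mimacro as mm

p = mm.default_params()

cert = mm.quadratic_bound(p)
print("verdict:", cert.verdict)
print("eigenvalues:", [f"{e:.4g}" for e in cert.eigenvalues])

print("\ncompleted-square slack per monomial:")
for mono, row in mm.sos_decomposition_check(p).items():
    flag = "  <-- overdrawn" if abs(row["slack"]) > 0.01 else ""
    print(f"  {mono:5s} bound {row['bound']:8.4f}  sos {row['sos']:8.4f}"
          f"  slack {row['slack']:+8.4f}{flag}")

rep = mm.pointwise_bound_dominates(p, n_samples=1000, seed=1)
print(f"\npointwise domination on 1000 random orthant states: "
      f"{rep['n_violations']} violations (dominates={rep['dominates']})")
print("worst violating state:", rep["worst_state"])
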