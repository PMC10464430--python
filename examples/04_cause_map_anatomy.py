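"""Look inside the cause map: targets, packages and combination rules.

Shows how individual garbage codes are routed — predefined ICD targets
(C55), MCOD packages (N19), drug-death combination rules (X42 + T40) — and
builds a target distribution by hand for one stratum.
"""

import gcredist as g
from gcredist import DeathRecord

cm = g.demo_map()

e = cm.match("C55")
print("C55 (malignant neoplasm of uterus, part unspecified):",
      e.idd_class, "->", list(e.target_codes))
e = cm.match("N19")
print("N19 (unspecified kidney failure):", e.idd_class,
      "-> package", repr(e.package_id), "=", list(cm.packages[e.package_id][1]))
print("R99:", cm.match("R99").idd_class, "(no a-priori information)")

rec = DeathRecord("x", 2004, 31, "male", "north", "X42",
                  mcod=[("T401", "associated")])
out = g.apply_combination_rules(rec, cm)
print(f"\ncombination rule: UC {rec.underlying_cause} + MCOD T40.1 -> UC "
      f"{out.underlying_cause} ({g.map_underlying_cause(out, cm).cause_l4})")

# a hand-built pool: 30 cervical vs 70 corpus-uteri cancer deaths
pool = [DeathRecord(f"p{i}", 2000 + i % 5, 55, "female", "north",
                    "C539" if i < 30 else "C549") for i in range(100)]
dist = g.build_target_distribution(
    list(zip(pool, g.classify_records(pool, cm))), year=2004,
    stratum=g.Stratum("45-64", "female"), cause_map=cm, restrict_to=["C53", "C54"],
)
print("\ntarget distribution for a C55 death (female, 45-64):")
for cause, p in dist.masses.items():
    print(f"  {cause:<18} {p:.2f}  (window support {dist.support_counts[cause]:.0f})")
print("A C55 death in this stratum is assigned cervical cancer with "
      f"probability {dist.masses['cervical_cancer']:.2f}.")
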