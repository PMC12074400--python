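# Default fuzzy-inference configuration for mobility-anomaly scoring.
#
# Inputs:
#   oal  — observed/historical activity ratio (1.0 = as active as usual).
#   dist — Euclidean deviation between observed and forecast place vectors,
#          normalized by (HAL + 1) so the scale is portable across homes:
#          ordinary stochastic jitter lands around 0.3-0.5, while total
#          inactivity in a normally busy hour lands around 0.75-0.95.
# Output:
#   pa — probability of a mobility anomaly on [0, 1].
#
# Membership sets are trapezoids (a, b, c, d); adjacent sets form a Ruspini
# partition (memberships sum to 1) over each input universe.
oal:
  universe: [0.0, 2.0]
  sets:
    Low:    [0.0, 0.0, 0.3, 0.6]
    Medium: [0.3, 0.6, 0.9, 1.2]
    High:   [0.9, 1.2, 2.0, 2.0]
dist:
  universe: [0.0, 2.0]
  sets:
    Low:    [0.0, 0.0, 0.3, 0.5]
    Medium: [0.3, 0.5, 0.55, 0.75]
    High:   [0.55, 0.75, 2.0, 2.0]
pa:
  universe: [0.0, 1.0]
  sets:
    Low:    [0.0, 0.0, 0.25, 0.5]
    Medium: [0.25, 0.5, 0.5, 0.75]
    High:   [0.5, 0.75, 1.0, 1.0]
# Rule base: (OAL label, Dist label) -> PA label.
rules:
  - [Low, Low, Medium]
  - [Low, Medium, Medium]
  - [Low, High, High]
  - [Medium, Low, Low]
  - [Medium, Medium, Medium]
  - [Medium, High, Medium]
  - [High, Low, Low]
  - [High, Medium, Low]
  - [High, High, Low]
alert_threshold: 0.7
dist_normalization: hal_plus_one   # or: none
inference: product_sum             # or: min_max (classic Mamdani)
epsilon: 1.0e-6                    # "quiet hour" tolerance for OAL
oal_cap: 2.0                       # OAL when HAL ~ 0 but activity observed
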