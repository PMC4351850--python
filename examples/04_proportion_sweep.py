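"""Dose response: suppression versus daily release proportion.

Sweeps a late-acting female-killing (LFK) campaign over release
proportions at a reduced scale and prints the final suppression factor
per proportion — more released males suppress more, with diminishing
returns once the response flattens.
"""

from sitsim import CampaignConfig, SITImplementation, SweepSpec, run_sweep

base = CampaignConfig(
    carrying_capacity=5000.0,
    burn_in_days=120,
    campaign_days=120,
    master_seed=13,
)
spec = SweepSpec(
    implementations=(SITImplementation.LFK,),
    proportions=(0.1, 0.3, 0.5, 0.7),
    competitiveness_levels=(1.0,),
    replicates=3,
)
grid = run_sweep(spec, base)

print("LFK, competitiveness 1.0, 120-day campaign, 3 replicates:")
print(f"{'proportion':>10} {'released/day':>13} {'suppression':>12} {'elimination':>12}")
for _, row in grid.iterrows():
    print(
        f"{row['release_proportion']:>10.1f} {row['release_number']:>13d} "
        f"{row['suppression_factor']:>12.3f} {str(row['elimination']):>12}"
    )
print("\n(suppression factor: wild-type adult females vs control over the final window)")
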