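"""Medium supplementation and the H2/ethanol secretion tradeoff.

Supplementing a metabolite opens its exchange to [-20, 0]: free uptake,
but production thermodynamically blocked.  The tradeoff scan fixes H2
escape across its viable range and re-optimises growth at each point.
"""

from thermoflux import make_fermentation_toy, media_supplementation_scan, tradeoff_scan

toy = make_fermentation_toy()

print("single-metabolite supplementation (ethanol yield = max ethanol / Z):")
for res in media_supplementation_scan(toy, None, ["ac", "lac", "h2"], pair_depth=1):
    if res.Z is None:
        print(f"  +{','.join(res.supplements):6s} {res.status}")
    else:
        print(
            f"  +{','.join(res.supplements):6s} Z = {res.Z:5.2f}  "
            f"max ethanol yield = {res.ethanol_yield:5.2f} mmol/gDW"
        )
print("-> blocking acetate production (by supplying acetate) reroutes")
print("   acetyl-CoA to ethanol: yield rises from 0 to 1, at a growth cost.")

print()
print("H2/ethanol tradeoff (H2 escape fixed, growth re-maximised):")
df = tradeoff_scan(toy, None, "EX_h2", "EX_etoh", n_points=9)
print(df[["EX_h2", "Z", "EX_etoh_min", "EX_etoh_max"]].to_string(index=False))
print("-> growth is concave in the fixed H2 flux; at the global optimum")
print("   ethanol is zero, and closing H2 escape pins ethanol at 10.")
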