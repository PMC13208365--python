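"""Generate a synthetic scene and check detection against its ground truth.

Every planned contact records its realized (rasterized) gap, so the
detector's output can be compared with the analytically expected contact
type: close below 15 nm, loose below 80 nm, nothing beyond.
"""

from mercquant import MercParams, generate_scene, single_contact_spec, summarize_mercs

params = MercParams(close_nm=15, loose_nm=80)
print(f"thresholds: close < {params.close_nm} nm, loose < {params.loose_nm} nm\n")
print(f"{'planned gap':>12} {'realized gap':>13} {'expected':>9} {'detected':>9}")
for gap in (5.0, 14.0, 20.0, 79.0, 100.0):
    mask, truth = generate_scene(single_contact_spec(gap, seed=7))
    contact = truth.contacts[0]
    expected = contact.expected_type(params, mask.calibration) or "none"
    report = summarize_mercs(mask, params)
    detected = (
        "close" if report.n_close else ("loose" if report.n_loose else "none")
    )
    print(f"{gap:>10.0f} nm {contact.realized_gap_px:>10.2f} px "
          f"{expected:>9} {detected:>9}")
print()
print("Realized gaps stay within half a pixel of the plan, so each scene's")
print("detection outcome is predictable from its planned geometry alone.")
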