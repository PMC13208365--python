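"""Quantify mitochondria-ER contacts in a single label mask.

Builds a small synthetic scene with two planned contacts — one at a 10 nm
gap (a close contact, < 15 nm) and one at 30 nm (a loose contact, between
15 and 80 nm) — then runs the full detector and prints the per-image
report fields.
"""

from mercquant import MercParams, SceneSpec, PlannedContact, generate_scene, summarize_mercs

spec = SceneSpec(
    image_shape=(320, 320),
    n_mitochondria=2,
    planned_contacts=(
        PlannedContact(mito_index=0, gap_nm=10.0, arc_span_deg=70.0),
        PlannedContact(mito_index=1, gap_nm=30.0, arc_span_deg=90.0),
    ),
    n_free_er=1,
    seed=42,
)
mask, truth = generate_scene(spec)
report = summarize_mercs(mask, MercParams(close_nm=15, loose_nm=80))

print(f"image: {report.image_id}  ({mask.shape[0]}x{mask.shape[1]} px, "
      f"{mask.calibration.pixel_size_nm} nm/px)")
print(f"mitochondria: {report.n_mitochondria}  total area {report.mito_area_nm2:.0f} nm^2")
print(f"ER objects:   {report.n_er_objects}  total area {report.er_area_nm2:.0f} nm^2")
print(f"close contacts (N_C1): {report.n_close}   total length (L_C1) {report.len_close_nm:.1f} nm")
print(f"loose contacts (N_C2): {report.n_loose}   total length (L_C2) {report.len_loose_nm:.1f} nm")
print(f"total mitochondrial contour: {report.total_mito_contour_nm:.1f} nm")
print()
print("The 10 nm tubule is reported as a close (first-type) contact and the")
print("30 nm tubule as a loose (second-type) contact; contour pixels flanking")
print("a close contact fall in the 15-80 nm band, so short loose segments can")
print("border a close one.  The free ER tubule is farther than 80 nm from")
print("every mitochondrion and contributes nothing.  L_C1 + L_C2 is the")
print("mitochondrial boundary length engaged in contacts.")
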