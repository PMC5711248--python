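# Default synthetic phantom: a single axial head-and-neck-like slice.
# Distances in mm; prescriptions in Gy (total over 33 fractions).
shape: [88, 96]
spacing_mm: [2.5, 2.5]
body_radii_mm: [90.0, 105.0]
body_center_mm: [0.0, 0.0]
ctv1_center_mm: [0.0, 20.0]
ctv1_radius_mm: 24.0
node2_offset_mm: [42.0, 0.0]
node2_radius_mm: 16.0
node3_offset_mm: [52.0, -28.0]
node3_radius_mm: 14.0
laterality: bilateral
serial_oar_center_mm: [0.0, -20.0]
serial_oar_radius_mm: 5.0
parotid_offset_mm: [60.0, -28.0]
parotid_radius_mm: 12.0
ctv_to_ptv_margin_mm: 3.0
prv_margin_mm: 5.0
rind_thickness_mm: 10.0
prescriptions_gy: [70.0, 63.0, 56.0]
fractions: 33
seed: 0
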