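# Smartphone cameras of the smartphone validation study.  Focal lengths are
# actual (not 35 mm-equivalent) values; one phone lacks usable front-camera
# specifications and so declares no front camera.  Front and back cameras use
# different acquisition distance sets.
phones:
  - name: "iPhone 5"
    back: {focal_length_mm: 4.15, pixel_size_um: 1.4}
    front: {focal_length_mm: 2.18, pixel_size_um: 1.8}
  - name: "iPhone XR"
    back: {focal_length_mm: 4.25, pixel_size_um: 1.4}
  - name: "Moto G9 Plus"
    back: {focal_length_mm: 5.53, pixel_size_um: 1.6}
    front: {focal_length_mm: 3.78, pixel_size_um: 2.0}
  - name: "Oppo A57"
    back: {focal_length_mm: 3.46, pixel_size_um: 1.1}
    front: {focal_length_mm: 3.57, pixel_size_um: 1.0}
  - name: "Samsung Galaxy A31"
    back: {focal_length_mm: 4.60, pixel_size_um: 1.6}
    front: {focal_length_mm: 3.80, pixel_size_um: 2.0}
front_distances_m: [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.9, 1.1, 1.3]
back_distances_m: [0.3, 0.5, 0.7, 1.0, 2.0, 4.0, 6.0, 10.0]
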