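# Full-frame DSLR bodies and lens configurations of the DSLR validation study.
# Pixel pitches and sensor dimensions are manufacturer values; each zoom lens
# contributes two configurations (its minimum and maximum focal length).
bodies:
  - name: "Canon EOS 6D"
    pixel_size_um: 6.55
    sensor_mm: [35.8, 23.9]
    lenses:
      - {label: "prime_50", type: prime, focal_length_mm: 50}
      - {label: "prime_85", type: prime, focal_length_mm: 85}
      - {label: "prime_100", type: prime, focal_length_mm: 100}
      - {label: "zoom_min_24", type: zoom_min, focal_length_mm: 24}
      - {label: "zoom_max_105", type: zoom_max, focal_length_mm: 105}
  - name: "Canon EOS 6D Mark II"
    pixel_size_um: 5.67
    sensor_mm: [36.0, 24.0]
    lenses:
      - {label: "prime_50", type: prime, focal_length_mm: 50}
      - {label: "prime_85", type: prime, focal_length_mm: 85}
      - {label: "prime_100", type: prime, focal_length_mm: 100}
      - {label: "zoom_min_24", type: zoom_min, focal_length_mm: 24}
      - {label: "zoom_max_105", type: zoom_max, focal_length_mm: 105}
  - name: "Nikon D780"
    pixel_size_um: 5.90
    sensor_mm: [35.9, 23.9]
    lenses:
      - {label: "prime_50", type: prime, focal_length_mm: 50}
      - {label: "prime_85", type: prime, focal_length_mm: 85}
      - {label: "prime_105", type: prime, focal_length_mm: 105}
      - {label: "zoom_min_24", type: zoom_min, focal_length_mm: 24}
      - {label: "zoom_max_120", type: zoom_max, focal_length_mm: 120}
distances_m: [1, 2, 3, 4, 6, 10]
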