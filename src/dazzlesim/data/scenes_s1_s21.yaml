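scenes:
- scene_id: S-1
  ambient_luminance: 0.005
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-2
  ambient_luminance: 0.05
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-3
  ambient_luminance: 0.5
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-4
  ambient_luminance: 4.55
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-5
  ambient_luminance: 49.76
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-6
  ambient_luminance: 491.52
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-7
  ambient_luminance: 13.14
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-8
  ambient_luminance: 13.14
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-9
  ambient_luminance: 13.14
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-10
  ambient_luminance: 13.14
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-11
  ambient_luminance: 13.14
  target_contrast: 0.89
  incidence_angle: 6.0
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-12
  ambient_luminance: 13.14
  target_contrast: 0.89
  incidence_angle: 12.0
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-13
  ambient_luminance: 13.14
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 40.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-14
  ambient_luminance: 13.14
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 50.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-15
  ambient_luminance: 13.14
  target_contrast: 0.89
  incidence_angle: 0.5
  age: 60.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-16
  ambient_luminance: 0.005
  target_contrast: 0.4
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-17
  ambient_luminance: 0.05
  target_contrast: 0.4
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-18
  ambient_luminance: 0.5
  target_contrast: 0.4
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-19
  ambient_luminance: 4.55
  target_contrast: 0.4
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-20
  ambient_luminance: 49.76
  target_contrast: 0.4
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
- scene_id: S-21
  ambient_luminance: 491.52
  target_contrast: 0.4
  incidence_angle: 0.5
  age: 30.0
  pigmentation: 0.5
  target_size_m: 0.24
  viewing_distance_m: 5.0
  wavelength: 532.0
  power_mw: 100.0
  divergence_mrad: 1.5
  distance_m: null
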