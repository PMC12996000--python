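# Landsat 8/9 OLI Collection-2 Level-2 band map
sensor_id: L8OLI
entries:
  - {role: blue,     file_pattern: "*SR_B2*.tif",   native_resolution: 30, wavelength: 482,  scale: 2.75e-5, offset: -0.2}
  - {role: green,    file_pattern: "*SR_B3*.tif",   native_resolution: 30, wavelength: 561,  scale: 2.75e-5, offset: -0.2}
  - {role: red,      file_pattern: "*SR_B4*.tif",   native_resolution: 30, wavelength: 655,  scale: 2.75e-5, offset: -0.2}
  - {role: nir,      file_pattern: "*SR_B5*.tif",   native_resolution: 30, wavelength: 865,  scale: 2.75e-5, offset: -0.2}
  - {role: swir1,    file_pattern: "*SR_B6*.tif",   native_resolution: 30, wavelength: 1609, scale: 2.75e-5, offset: -0.2}
  - {role: qa_pixel, file_pattern: "*QA_PIXEL*.tif", native_resolution: 30, wavelength: 0,   scale: 1.0,     offset: 0.0}
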