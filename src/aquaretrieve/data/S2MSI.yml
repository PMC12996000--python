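# Sentinel-2 MSI band map (surface-reflectance GeoTIFF naming, e.g. ACOLITE output)
sensor_id: S2MSI
entries:
  - {role: blue,     file_pattern: "*B02*.tif", native_resolution: 10, wavelength: 492,  scale: 1.0, offset: 0.0}
  - {role: green,    file_pattern: "*B03*.tif", native_resolution: 10, wavelength: 560,  scale: 1.0, offset: 0.0}
  - {role: red,      file_pattern: "*B04*.tif", native_resolution: 10, wavelength: 665,  scale: 1.0, offset: 0.0}
  - {role: rededge,  file_pattern: "*B05*.tif", native_resolution: 20, wavelength: 704,  scale: 1.0, offset: 0.0}
  - {role: nir,      file_pattern: "*B08*.tif", native_resolution: 10, wavelength: 833,  scale: 1.0, offset: 0.0}
  - {role: swir1,    file_pattern: "*B11*.tif", native_resolution: 20, wavelength: 1614, scale: 1.0, offset: 0.0}
  - {role: scl,      file_pattern: "*SCL*.tif", native_resolution: 20, wavelength: 0,    scale: 1.0, offset: 0.0}
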