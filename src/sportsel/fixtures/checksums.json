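{
 "estimates_full.json": "bd5d09f64df5f31b46a9015dbbc10ac1600f393c8b49b082d6469f876f279f29",
 "profiles.json": "a341896c35fa673bd0e6497759d8359083a51da4fc8743a86c1fd5d32887a76d",
 "bmi_coefficients.json": "a92c7b42296a13b9c6eec2fcbc174e83a903ff7a9ec60479c4e442730d3ddb8f",
 "vigour_by_events.json": "14ab9d4510a4bcb7474d78e85bd837e3f652789ce7c65cf1aedf8a3cc3d1a808"
}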