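{
  "description": "Catalog of the 13 optimal implant sites of the canine atlantoaxial region. Numbered sites (0-9) follow the validation-table footnote: C1 pedicular/lateral mass (0-1), C1-C2 transarticular (2-3), C2 cranial articular surface (4-5), C2 pedicular (6-7), C2 parasagittal caudal vertebral body (8-9); even numbers are right-sided. The three strictly sagittal sites carry name tags. 'frame' names the vertebral coordinate system in which projected angles are measured (transarticular implants project in the C1 frame). 'projection_pair' lists the reported angle(s); the X axis of the C1 frame is anatomically the ventrodorsal axis and of the C2 frame the craniocaudal axis.",
  "sites": [
    {"site_id": "0", "corridor": "C1 lateral mass (pedicular)", "vertebra": "C1", "laterality": "right", "frame": "C1", "shape": "pyramid", "projection_pair": ["sagittal", "dorsal"], "sagittal_site": false, "canal_directed": false},
    {"site_id": "1", "corridor": "C1 lateral mass (pedicular)", "vertebra": "C1", "laterality": "left", "frame": "C1", "shape": "pyramid", "projection_pair": ["sagittal", "dorsal"], "sagittal_site": false, "canal_directed": false},
    {"site_id": "2", "corridor": "C1-C2 transarticular", "vertebra": "C1-C2", "laterality": "right", "frame": "C1", "shape": "pyramid", "projection_pair": ["sagittal", "dorsal"], "sagittal_site": false, "canal_directed": false},
    {"site_id": "3", "corridor": "C1-C2 transarticular", "vertebra": "C1-C2", "laterality": "left", "frame": "C1", "shape": "pyramid", "projection_pair": ["sagittal", "dorsal"], "sagittal_site": false, "canal_directed": false},
    {"site_id": "4", "corridor": "C2 cranial articular surface", "vertebra": "C2", "laterality": "right", "frame": "C2", "shape": "hemi_ellipsoid", "projection_pair": ["sagittal", "dorsal"], "sagittal_site": false, "canal_directed": false},
    {"site_id": "5", "corridor": "C2 cranial articular surface", "vertebra": "C2", "laterality": "left", "frame": "C2", "shape": "hemi_ellipsoid", "projection_pair": ["sagittal", "dorsal"], "sagittal_site": false, "canal_directed": false},
    {"site_id": "6", "corridor": "C2 pedicle", "vertebra": "C2", "laterality": "right", "frame": "C2", "shape": "prism", "projection_pair": ["sagittal", "dorsal"], "sagittal_site": false, "canal_directed": false},
    {"site_id": "7", "corridor": "C2 pedicle", "vertebra": "C2", "laterality": "left", "frame": "C2", "shape": "prism", "projection_pair": ["sagittal", "dorsal"], "sagittal_site": false, "canal_directed": false},
    {"site_id": "8", "corridor": "C2 caudal vertebral body (parasagittal)", "vertebra": "C2", "laterality": "right", "frame": "C2", "shape": "prism", "projection_pair": ["sagittal", "dorsal"], "sagittal_site": false, "canal_directed": false},
    {"site_id": "9", "corridor": "C2 caudal vertebral body (parasagittal)", "vertebra": "C2", "laterality": "left", "frame": "C2", "shape": "prism", "projection_pair": ["sagittal", "dorsal"], "sagittal_site": false, "canal_directed": false},
    {"site_id": "c1_ventral_arch", "corridor": "C1 ventral arch", "vertebra": "C1", "laterality": "midline", "frame": "C1", "shape": "prism", "projection_pair": ["sagittal"], "sagittal_site": true, "canal_directed": true},
    {"site_id": "c2_cranial_body", "corridor": "C2 cranial vertebral body", "vertebra": "C2", "laterality": "midline", "frame": "C2", "shape": "hemi_ellipsoid", "projection_pair": ["sagittal"], "sagittal_site": true, "canal_directed": true},
    {"site_id": "c2_caudal_body_axial", "corridor": "C2 caudal vertebral body (sagittal)", "vertebra": "C2", "laterality": "midline", "frame": "C2", "shape": "prism", "projection_pair": ["sagittal"], "sagittal_site": true, "canal_directed": false}
  ]
}
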