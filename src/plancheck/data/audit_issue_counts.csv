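category,section,pre_count,with_count
Missing/incorrect contours or Booleans,unrelated,21,7
"Missing/incorrect documentation, billing, database logs",unrelated,64,49
Prescription problems,unrelated,17,20
"Plan quality: DVH, isodose lines, beam arrangement, missing flash",unrelated,13,5
"R&V details: treatment time, imaging templates, scheduling, carepaths, breakpoints",unrelated,11,9
"DRR quality, window/level",unrelated,5,2
"Treatment field technical parameters (names, MLC, intensities, jaws, etc.)",unrelated,7,11
"Setup field technical parameters (angles, names, etc.)",unrelated,6,2
Miscellaneous,unrelated,6,9
Completion status of non-clinical courses,related,17,3
DRR overlays,related,5,1
"Treatment field technical parameters: bolus, couch coordinates",related,2,0
Setup field technical parameters: imager position,related,2,1
Reference points: missing or incorrect contributions,related,5,2
Incorrect grid size,related,3,0
Course/plan does not follow naming conventions,related,10,5
Incorrect tolerance tables,related,6,1
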