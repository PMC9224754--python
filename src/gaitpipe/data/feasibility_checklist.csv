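area,group,question,loc1,loc2,loc3,loc4,loc5,loc6
implementation,location_features,Does the location contain enough space to produce the designed motion capture volume?,yes,yes,yes,yes,yes,yes
implementation,location_features,Does the space have an accessible power source to operate equipment within reach of a 20-foot extension cord?,yes,yes,yes,yes,yes,yes
implementation,location_features,"Does the space have a constant, sufficient light source?",yes,no,yes,yes,yes,yes
implementation,system_mobility,"Could equipment and supplies be packed, transported, and couriered to and from testing sites?",yes,yes,yes,yes,yes,yes
implementation,data_management,Could recorded data be securely stored?,yes,yes,yes,yes,yes,yes
practicality,participant_investment,Could the participant complete the experiment without additional travel?,yes,yes,yes,yes,yes,yes
practicality,participant_investment,Was the average time commitment under 30 min?,yes,yes,yes,yes,no,yes
practicality,participant_investment,Were participants tested in the clothes in which they arrived?,yes,yes,yes,yes,yes,yes
practicality,research_investment,"Could the system be unpacked, set up, calibrated and ready for use within 1 hour of arriving on site?",yes,yes,yes,yes,yes,yes
practicality,research_investment,"Could the system be mobilized, set up and experiment performed with a minimum of four people?",yes,yes,yes,yes,no,yes
practicality,research_investment,Was it possible to access and recruit a minimum of 10 participants each time the equipment was set up?,yes,yes,yes,yes,yes,no
practicality,research_investment,Could the 3D kinematic data be quickly extracted and efficiently processed?,yes,no,yes,yes,yes,yes
expansion,kinematics_3d,Did the system produce a full-body 3D kinematic model outside a controlled laboratory setting?,yes,yes,yes,yes,yes,yes
expansion,kinematics_3d,Did the system produce a full-body 3D kinematic model in the presence of background activity?,yes,yes,yes,yes,yes,yes
expansion,diverse_population,Did the location provide access to a sample population representative of the surrounding metropolitan area?,yes,yes,yes,yes,yes,yes
expansion,diverse_population,"Did the system produce a full-body 3D kinematic model for participants using an assistive device (walker, cane)?",yes,yes,yes,yes,yes,yes
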