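task,metric,group,mean,sd,n
task3,path_length_left,robotic,3813,1508,15
task3,path_length_left,laparoscopic,6862,3261,26
task3,path_length_left,novice,5544,2397,29
task3,path_length_right,robotic,4784,1851,15
task3,path_length_right,laparoscopic,5941,2965,26
task3,path_length_right,novice,5377,2937,29
task3,movements_left,robotic,344,127,15
task3,movements_left,laparoscopic,494,212,26
task3,movements_left,novice,438,164,29
task3,movements_right,robotic,386,156,15
task3,movements_right,laparoscopic,501,229,26
task3,movements_right,novice,450,182,29
task3,entrance_and_exit_points,robotic,28,4,15
task3,entrance_and_exit_points,laparoscopic,32,7,26
task3,entrance_and_exit_points,novice,31,5,29
task3,distance_scope_and_tissue,robotic,94,20,15
task3,distance_scope_and_tissue,laparoscopic,116,10,26
task3,distance_scope_and_tissue,novice,120,1,29
task3,instrument_collisions,robotic,9,11,15
task3,instrument_collisions,laparoscopic,32,32,26
task3,instrument_collisions,novice,24,19,29
task3,times_out_of_view,robotic,32,34,15
task3,times_out_of_view,laparoscopic,16,11,26
task3,times_out_of_view,novice,10,16,29
task3,unnecessary_piercing,robotic,10.8,8.4,15
task3,unnecessary_piercing,laparoscopic,14.4,11.1,26
task3,unnecessary_piercing,novice,13.1,10.1,29
task3,suture_breakage,robotic,0.0,0.0,15
task3,suture_breakage,laparoscopic,0.0,0.2,26
task3,suture_breakage,novice,0.0,0.2,29
task3,precise_needle_passages,robotic,10.3,3.0,15
task3,precise_needle_passages,laparoscopic,12.0,3.9,26
task3,precise_needle_passages,novice,12.4,3.0,29
task3,needle_passages,robotic,14.1,1.8,15
task3,needle_passages,laparoscopic,16.1,3.3,26
task3,needle_passages,novice,15.3,2.5,29
task3,total_time,robotic,423,180,15
task3,total_time,laparoscopic,580,250,26
task3,total_time,novice,573,210,29
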