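task,metric,group,mean,sd,n
task1,path_length_left,robotic,1655,478,15
task1,path_length_left,laparoscopic,3469,1577,26
task1,path_length_left,novice,4157,1870,29
task1,path_length_right,robotic,2196,771,15
task1,path_length_right,laparoscopic,3879,2144,26
task1,path_length_right,novice,3885,1720,29
task1,movements_left,robotic,168,57,15
task1,movements_left,laparoscopic,342,159,26
task1,movements_left,novice,422,176,29
task1,movements_right,robotic,234,76,15
task1,movements_right,laparoscopic,394,191,26
task1,movements_right,novice,425,170,29
task1,inaccurate_punctures,robotic,5.5,3.1,15
task1,inaccurate_punctures,laparoscopic,10.9,7.3,26
task1,inaccurate_punctures,novice,13.4,9.4,29
task1,instrument_collisions,robotic,4.0,3.9,15
task1,instrument_collisions,laparoscopic,13.9,13.9,26
task1,instrument_collisions,novice,15.9,10.5,29
task1,times_out_of_view,robotic,1.3,1.0,15
task1,times_out_of_view,laparoscopic,2.4,4.0,26
task1,times_out_of_view,novice,1.7,2.1,29
task1,needle_precision,robotic,63,15,15
task1,needle_precision,laparoscopic,48,20,26
task1,needle_precision,novice,47,19,29
task1,total_errors,robotic,13.9,12.1,15
task1,total_errors,laparoscopic,11.1,5.5,26
task1,total_errors,novice,11.3,3.3,29
task1,total_time,robotic,265,92,15
task1,total_time,laparoscopic,475,219,26
task1,total_time,novice,597,225,29
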