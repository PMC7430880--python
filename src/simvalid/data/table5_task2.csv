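task,metric,group,mean,sd,n
task2,entrance_and_exit_points,robotic,5.7,2.1,14
task2,entrance_and_exit_points,laparoscopic,7.7,4.6,26
task2,entrance_and_exit_points,novice,11.4,8.8,28
task2,dropped_needles,robotic,3.6,3.5,14
task2,dropped_needles,laparoscopic,5.8,6.8,26
task2,dropped_needles,novice,10.8,10.4,28
task2,unnecessary_piercing,robotic,2.6,2.6,14
task2,unnecessary_piercing,laparoscopic,6.3,5.0,26
task2,unnecessary_piercing,novice,10.4,8.4,28
task2,needle_out_of_view,robotic,3.3,4.8,14
task2,needle_out_of_view,laparoscopic,6.2,9.9,26
task2,needle_out_of_view,novice,8.1,11.2,28
task2,suture_breakage,robotic,0.0,0.0,14
task2,suture_breakage,laparoscopic,0.3,0.5,26
task2,suture_breakage,novice,0.6,1.2,28
task2,total_knots,robotic,1.5,0.9,14
task2,total_knots,laparoscopic,1.3,0.7,26
task2,total_knots,novice,1.1,0.4,28
task2,surgeon_knots,robotic,0.6,1.0,14
task2,surgeon_knots,laparoscopic,0.6,0.8,26
task2,surgeon_knots,novice,0.8,0.6,28
task2,needle_precision,robotic,96,8,14
task2,needle_precision,laparoscopic,79,30,26
task2,needle_precision,novice,90,13,28
task2,total_time,robotic,171,77,14
task2,total_time,laparoscopic,277,172,26
task2,total_time,novice,546,328,28
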